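"""Road networks, transport modes, and shortest travel-time matrices.

Coordinates are planar meters (projected x/y); geographic input must be
pre-projected by the caller, which is adequate at single-city scale.
Travel time on an edge is ``length / speed`` at a constant per-edge speed
(no turn penalties or traffic). Pedestrians may traverse every street in
both directions; vehicular modes (car, bicycle, ambulance) must respect
one-way restrictions. Unreachable pairs are ``+inf``, never a sentinel.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "TravelMode",
    "DEFAULT_SPEEDS_KMH",
    "get_mode",
    "Edge",
    "RoadNetwork",
    "SitePoint",
    "PointSet",
    "TravelTimeMatrix",
    "snap_points",
    "shortest_travel_time",
    "travel_time_matrix",
    "read_network_geojson",
    "write_network_geojson",
    "read_points_geojson",
    "write_points_geojson",
]

#: Default speeds in km/h. Walking at 10 km/h is the standardized bystander
#: speed of the study design (brisk running pace); the ambulance averages
#: 50 km/h in urban conditions. Bicycle and car are urban-plausible choices
#: for the modes the study mentions but does not parameterize.
DEFAULT_SPEEDS_KMH: dict[str, float] = {
    "walk": 10.0,
    "bicycle": 15.0,
    "car": 40.0,
    "ambulance": 50.0,
}

#: Modes bound by one-way restrictions. Pedestrians are not.
VEHICULAR_MODES = frozenset({"bicycle", "car", "ambulance"})


@dataclass(frozen=True)
class TravelMode:
    """A transport mode: a name and a default speed in km/h.

    ``directed`` is True when the mode must respect one-way streets.
    """

    name: str
    speed_kmh: float

    def __post_init__(self) -> None:
        if self.speed_kmh <= 0:
            raise ValueError(f"mode {self.name!r}: speed must be positive")

    @property
    def directed(self) -> bool:
        return self.name in VEHICULAR_MODES


def get_mode(name: str, speed_kmh: float | None = None) -> TravelMode:
    """Return a :class:`TravelMode` by name, optionally overriding its speed.

    Raises ``ValueError`` for a name outside {walk, bicycle, car, ambulance}.
    """
    if name not in DEFAULT_SPEEDS_KMH:
        raise ValueError(
            f"unknown mode {name!r}; expected one of {sorted(DEFAULT_SPEEDS_KMH)}"
        )
    return TravelMode(name, DEFAULT_SPEEDS_KMH[name] if speed_kmh is None else speed_kmh)


@dataclass(frozen=True)
class Edge:
    """A street segment between two nodes.

    ``oneway=True`` restricts vehicular traversal to the u→v direction.
    ``speed_override`` maps mode name → km/h for segment-specific limits.
    """

    u: str
    v: str
    length_m: float
    oneway: bool = False
    speed_override: dict[str, float] | None = None

    def speed_for(self, mode: TravelMode) -> float:
        if self.speed_override and mode.name in self.speed_override:
            return self.speed_override[mode.name]
        return mode.speed_kmh

    def time_s(self, mode: TravelMode) -> float:
        """Traversal time in seconds at the mode's effective speed."""
        return self.length_m * 3.6 / self.speed_for(mode)


@dataclass
class RoadNetwork:
    """A planar street graph: node coordinates plus a list of edges."""

    nodes: dict[str, tuple[float, float]]
    edges: list[Edge]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for e in self.edges:
            if e.length_m <= 0:
                raise ValueError(f"edge {e.u}-{e.v}: length must be > 0")
            if e.u not in self.nodes or e.v not in self.nodes:
                raise ValueError(f"edge {e.u}-{e.v}: endpoint not a declared node")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def bounding_box(self) -> tuple[float, float, float, float]:
        """(min_x, min_y, max_x, max_y) over node coordinates."""
        xs = [xy[0] for xy in self.nodes.values()]
        ys = [xy[1] for xy in self.nodes.values()]
        return min(xs), min(ys), max(xs), max(ys)

    def graph(self, mode: TravelMode) -> nx.DiGraph:
        """Directed graph with per-edge traversal time (s) for ``mode``.

        Walk traverses every edge in both directions regardless of one-way
        flags; vehicular modes traverse one-way edges only u→v.
        """
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            t = e.time_s(mode)
            _add_min_edge(g, e.u, e.v, t)
            if not (e.oneway and mode.directed):
                _add_min_edge(g, e.v, e.u, t)
        return g


def _add_min_edge(g: nx.DiGraph, u: str, v: str, t: float) -> None:
    # parallel segments collapse to the fastest one
    if not g.has_edge(u, v) or g[u][v]["time_s"] > t:
        g.add_edge(u, v, time_s=t)


@dataclass(frozen=True)
class SitePoint:
    """A located site: an OHCA demand point, a candidate AED site, or an
    ambulance station. ``snapped_node`` is set by :func:`snap_points`."""

    id: str
    x: float
    y: float
    kind: str  # demand | candidate | station
    snapped_node: str | None = None


@dataclass
class PointSet:
    """An ordered set of uniform-kind points; matrix axes follow its order."""

    points: list[SitePoint]
    crs_note: str = "planar meters (synthetic)"

    def __post_init__(self) -> None:
        ids = [p.id for p in self.points]
        if len(set(ids)) != len(ids):
            raise ValueError("point ids must be unique within a set")
        kinds = {p.kind for p in self.points}
        if len(kinds) > 1:
            raise ValueError(f"mixed point kinds in one set: {sorted(kinds)}")

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self):
        return iter(self.points)

    @property
    def ids(self) -> list[str]:
        return [p.id for p in self.points]

    @property
    def kind(self) -> str | None:
        return self.points[0].kind if self.points else None

    @property
    def snapped_nodes(self) -> list[str]:
        out = []
        for p in self.points:
            if p.snapped_node is None:
                raise ValueError(f"point {p.id} is not snapped")
            out.append(p.snapped_node)
        return out


def snap_points(network: RoadNetwork, points: PointSet) -> PointSet:
    """Snap each point to the Euclidean-nearest network node.

    Original coordinates are preserved; only ``snapped_node`` is filled.
    Exact distance ties break to the lexicographically lowest node id, so
    snapping is deterministic.
    """
    if not network.nodes:
        raise ValueError("no nodes to snap to")
    node_ids = sorted(network.nodes)
    coords = np.array([network.nodes[n] for n in node_ids], dtype=float)
    snapped = []
    for p in points:
        d2 = (coords[:, 0] - p.x) ** 2 + (coords[:, 1] - p.y) ** 2
        # argmin returns the first minimum; node_ids is sorted, so exact
        # ties resolve to the lowest id
        snapped.append(replace(p, snapped_node=node_ids[int(np.argmin(d2))]))
    return PointSet(snapped, crs_note=points.crs_note)


def shortest_travel_time(
    network: RoadNetwork, origin: str, dest: str, mode: TravelMode
) -> float:
    """Minimum travel time in seconds from ``origin`` to ``dest`` node.

    Dijkstra on the mode-specific directed graph; ``+inf`` when no path
    exists under the mode's traversal rules; 0 when origin equals dest.
    """
    for n in (origin, dest):
        if n not in network.nodes:
            raise KeyError(f"unknown node {n!r}")
    if origin == dest:
        return 0.0
    g = network.graph(mode)
    try:
        return float(nx.dijkstra_path_length(g, origin, dest, weight="time_s"))
    except nx.NetworkXNoPath:
        return math.inf


@dataclass
class TravelTimeMatrix:
    """Origin × destination travel times in seconds for one mode.

    ``t[i, j]`` follows the point-set orders; entries may be ``+inf``.
    """

    origins: PointSet
    destinations: PointSet
    mode: TravelMode
    t: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if self.t.shape != (len(self.origins), len(self.destinations)):
            raise ValueError("matrix shape does not match point-set sizes")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.t, index=self.origins.ids, columns=self.destinations.ids)

    def to_csv(self, path: str | Path, provenance: str | None = None) -> None:
        """Write as CSV (origin ids as rows, ``inf`` for unreachable)."""
        path = Path(path)
        with open(path, "w") as fh:
            if provenance:
                fh.write(f"# {provenance}\n")
            self.to_frame().to_csv(fh, lineterminator="\n")

    @staticmethod
    def read_csv(path: str | Path) -> pd.DataFrame:
        return pd.read_csv(path, index_col=0, comment="#")


def travel_time_matrix(
    network: RoadNetwork,
    origins: PointSet,
    destinations: PointSet,
    mode: TravelMode,
) -> TravelTimeMatrix:
    """All origin→destination shortest travel times for one mode.

    Points are snapped implicitly when needed. One Dijkstra per distinct
    origin node; repeated snap nodes share the computation.
    """
    if any(p.snapped_node is None for p in origins):
        origins = snap_points(network, origins)
    if any(p.snapped_node is None for p in destinations):
        destinations = snap_points(network, destinations)
    o_nodes = origins.snapped_nodes
    d_nodes = destinations.snapped_nodes
    g = network.graph(mode)
    t = np.full((len(o_nodes), len(d_nodes)), math.inf)
    dist_cache: dict[str, dict[str, float]] = {}
    for i, on in enumerate(o_nodes):
        if on not in dist_cache:
            dist_cache[on] = nx.single_source_dijkstra_path_length(g, on, weight="time_s")
        dists = dist_cache[on]
        for j, dn in enumerate(d_nodes):
            t[i, j] = dists.get(dn, math.inf)
    return TravelTimeMatrix(origins, destinations, mode, t)


# ---------------------------------------------------------------------------
# GeoJSON I/O


def write_network_geojson(
    network: RoadNetwork, path: str | Path, provenance: dict | None = None
) -> None:
    """Write the network as a FeatureCollection of LineString segments.

    Each edge becomes one two-point LineString with properties ``length_m``,
    ``oneway`` and optional ``maxspeed_<mode>`` overrides. Node identity is
    carried by exact endpoint coordinates, as in the reader.
    """
    feats = []
    for e in network.edges:
        props: dict = {"length_m": e.length_m, "oneway": e.oneway}
        if e.speed_override:
            for m, s in sorted(e.speed_override.items()):
                props[f"maxspeed_{m}"] = s
        feats.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "LineString",
                    "coordinates": [list(network.nodes[e.u]), list(network.nodes[e.v])],
                },
                "properties": props,
            }
        )
    fc: dict = {"type": "FeatureCollection", "features": feats}
    if provenance:
        fc["provenance"] = provenance
    _dump_json(fc, path)


def read_network_geojson(path: str | Path) -> RoadNetwork:
    """Read a LineString FeatureCollection into a :class:`RoadNetwork`.

    Nodes are derived from shared segment endpoints by exact coordinate
    match and assigned deterministic ids in sorted coordinate order.
    ``length_m`` is recomputed from the geometry when absent.
    """
    with open(path) as fh:
        fc = json.load(fh)
    coord_set: set[tuple[float, float]] = set()
    segments = []
    for feat in fc["features"]:
        geom = feat.get("geometry") or {}
        if geom.get("type") != "LineString":
            continue
        coords = [tuple(map(float, c)) for c in geom["coordinates"]]
        props = feat.get("properties") or {}
        coord_set.add(coords[0])
        coord_set.add(coords[-1])
        segments.append((coords, props))
    node_ids = {
        xy: f"n{i:06d}" for i, xy in enumerate(sorted(coord_set))
    }
    nodes = {nid: xy for xy, nid in node_ids.items()}
    edges = []
    for coords, props in segments:
        length = props.get("length_m")
        if length is None:
            length = sum(
                math.dist(coords[k], coords[k + 1]) for k in range(len(coords) - 1)
            )
        override = {
            k[len("maxspeed_"):]: float(v)
            for k, v in props.items()
            if k.startswith("maxspeed_")
        }
        edges.append(
            Edge(
                u=node_ids[coords[0]],
                v=node_ids[coords[-1]],
                length_m=float(length),
                oneway=bool(props.get("oneway", False)),
                speed_override=override or None,
            )
        )
    return RoadNetwork(nodes=nodes, edges=edges)


def write_points_geojson(
    points: PointSet, path: str | Path, provenance: dict | None = None
) -> None:
    """Write a PointSet as a FeatureCollection of Point features."""
    feats = []
    for p in points:
        props = {"id": p.id, "kind": p.kind}
        if p.snapped_node is not None:
            props["snapped_node"] = p.snapped_node
        feats.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [p.x, p.y]},
                "properties": props,
            }
        )
    fc: dict = {"type": "FeatureCollection", "features": feats}
    if provenance:
        fc["provenance"] = provenance
    _dump_json(fc, path)


def read_points_geojson(path: str | Path) -> PointSet:
    with open(path) as fh:
        fc = json.load(fh)
    pts = []
    for feat in fc["features"]:
        geom = feat["geometry"]
        if geom["type"] != "Point":
            continue
        props = feat.get("properties") or {}
        x, y = map(float, geom["coordinates"])
        pts.append(
            SitePoint(
                id=str(props["id"]),
                x=x,
                y=y,
                kind=str(props.get("kind", "demand")),
                snapped_node=props.get("snapped_node"),
            )
        )
    return PointSet(pts)


def _dump_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, sort_keys=True, indent=2)
        fh.write("\n")
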