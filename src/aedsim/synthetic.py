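"""Synthetic urban scenes: grid street networks, OHCA demand, AED
candidates, and an ambulance station.

The generator emulates a planned, grid-like city: a jittered node lattice
with horizontal/vertical streets, a configurable fraction of one-way
streets alternating direction (so vehicles are never trapped), demand
points sampled uniformly over a central region of the bounding box, AED
candidate sites on street corners, and a single station. Every output is
a pure function of its config and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import networkx as nx
import numpy as np

from aedsim.network import Edge, PointSet, RoadNetwork, SitePoint, get_mode

__all__ = [
    "CityConfig",
    "generate_grid_city",
    "sample_demand_points",
    "place_candidates",
    "place_station",
]


@dataclass
class CityConfig:
    """Parameters of a synthetic city scene.

    Defaults describe the replication scene: a ~4.8 km square grid of
    200 m blocks (city-center scale), 50 OHCA demand points in the
    central half of the bounding box, 150 candidate AED corners, and one
    ambulance station.
    """

    rows: int = 25
    cols: int = 25
    block_m: float = 200.0
    jitter_m: float = 15.0
    oneway_fraction: float = 0.3
    n_demand: int = 50
    n_candidates: int = 150
    n_stations: int = 1
    center_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rows < 2 or self.cols < 2:
            raise ValueError("grid must be at least 2x2")
        if not (0.0 <= self.oneway_fraction <= 1.0):
            raise ValueError("oneway_fraction must be in [0, 1]")
        if not (0.0 < self.center_fraction <= 1.0):
            raise ValueError("center_fraction must be in (0, 1]")
        if self.block_m <= 0:
            raise ValueError("block_m must be positive")
        if self.jitter_m < 0:
            raise ValueError("jitter_m must be nonnegative")

    def to_dict(self) -> dict:
        return asdict(self)


def _node_id(r: int, c: int) -> str:
    return f"n{r:03d}_{c:03d}"


def generate_grid_city(config: CityConfig) -> RoadNetwork:
    """Generate a jittered rows×cols lattice street network.

    Node coordinates are the lattice positions plus a uniform jitter of at
    most ``jitter_m`` per axis; edge lengths are exact Euclidean distances
    between the jittered endpoints. Each full street (a row or a column)
    is one-way with probability ``oneway_fraction``; one-way direction
    alternates with street parity, which preserves vehicular strong
    connectivity for moderate fractions. Strong connectivity under the car
    mode is verified and, if violated, the scene is regenerated with a
    derived seed (deterministically, so a fixed seed always yields the
    same network).
    """
    for attempt in range(50):
        net = _generate_once(config, config.seed + 7919 * attempt)
        if config.oneway_fraction == 0.0:
            return net
        if nx.is_strongly_connected(net.graph(get_mode("car"))):
            return net
    raise RuntimeError(
        "could not generate a strongly connected network; lower oneway_fraction"
    )


def _generate_once(config: CityConfig, seed: int) -> RoadNetwork:
    rng = np.random.default_rng(seed)
    rows, cols, b, j = config.rows, config.cols, config.block_m, config.jitter_m
    jx = rng.uniform(-j, j, size=(rows, cols)) if j > 0 else np.zeros((rows, cols))
    jy = rng.uniform(-j, j, size=(rows, cols)) if j > 0 else np.zeros((rows, cols))
    nodes = {
        _node_id(r, c): (c * b + jx[r, c], r * b + jy[r, c])
        for r in range(rows)
        for c in range(cols)
    }

    # Streets as units: row streets run west-east, column streets south-north.
    row_oneway = rng.random(rows) < config.oneway_fraction
    col_oneway = rng.random(cols) < config.oneway_fraction

    def dist(a: str, bnode: str) -> float:
        (x1, y1), (x2, y2) = nodes[a], nodes[bnode]
        return float(np.hypot(x2 - x1, y2 - y1))

    edges: list[Edge] = []
    for r in range(rows):
        forward = r % 2 == 0  # alternate one-way direction by street parity
        for c in range(cols - 1):
            u, v = _node_id(r, c), _node_id(r, c + 1)
            if row_oneway[r] and not forward:
                u, v = v, u
            edges.append(Edge(u, v, dist(u, v), oneway=bool(row_oneway[r])))
    for c in range(cols):
        forward = c % 2 == 0
        for r in range(rows - 1):
            u, v = _node_id(r, c), _node_id(r + 1, c)
            if col_oneway[c] and not forward:
                u, v = v, u
            edges.append(Edge(u, v, dist(u, v), oneway=bool(col_oneway[c])))
    return RoadNetwork(nodes=nodes, edges=edges)


def sample_demand_points(
    network: RoadNetwork, n: int, center_fraction: float, seed: int
) -> PointSet:
    """Sample ``n`` OHCA demand points uniformly over the central region.

    The central region is the concentric sub-rectangle spanning
    ``center_fraction`` of the network bounding box on each axis — the
    high-density city center where arrests are simulated. Points live in
    continuous space (snap to the network downstream).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0.0 < center_fraction <= 1.0):
        raise ValueError("center_fraction must be in (0, 1]")
    min_x, min_y, max_x, max_y = network.bounding_box()
    if max_x <= min_x or max_y <= min_y:
        raise ValueError("degenerate bounding box")
    cx, cy = (min_x + max_x) / 2.0, (min_y + max_y) / 2.0
    hw = (max_x - min_x) * center_fraction / 2.0
    hh = (max_y - min_y) * center_fraction / 2.0
    rng = np.random.default_rng(seed)
    xs = rng.uniform(cx - hw, cx + hw, size=n)
    ys = rng.uniform(cy - hh, cy + hh, size=n)
    width = max(3, len(str(n)))
    pts = [
        SitePoint(id=f"d{i + 1:0{width}d}", x=float(xs[i]), y=float(ys[i]), kind="demand")
        for i in range(n)
    ]
    return PointSet(pts)


def place_candidates(network: RoadNetwork, n: int, seed: int) -> PointSet:
    """Choose ``n`` distinct street corners as candidate AED sites.

    Stands in for a registry of public, non-residential establishments:
    a seeded sample of network nodes without replacement.
    """
    node_ids = sorted(network.nodes)
    if n > len(node_ids):
        raise ValueError(f"n={n} exceeds node count {len(node_ids)}")
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(len(node_ids), size=n, replace=False).tolist())
    width = max(3, len(str(n)))
    pts = []
    for i, idx in enumerate(chosen):
        nid = node_ids[idx]
        x, y = network.nodes[nid]
        pts.append(
            SitePoint(
                id=f"c{i + 1:0{width}d}", x=x, y=y, kind="candidate", snapped_node=nid
            )
        )
    return PointSet(pts)


def place_station(network: RoadNetwork, position: str = "corner", seed: int = 0) -> PointSet:
    """Place the single ambulance station.

    ``position`` is ``"corner"`` (node nearest the min-x/min-y corner),
    ``"centroid"`` (node nearest the bounding-box center), or an explicit
    node id.
    """
    min_x, min_y, max_x, max_y = network.bounding_box()
    if position == "corner":
        target = (min_x, min_y)
        nid = _nearest_node(network, target)
    elif position == "centroid":
        target = ((min_x + max_x) / 2.0, (min_y + max_y) / 2.0)
        nid = _nearest_node(network, target)
    elif position in network.nodes:
        nid = position
    else:
        raise ValueError(f"unknown station position {position!r}")
    x, y = network.nodes[nid]
    return PointSet(
        [SitePoint(id="s001", x=x, y=y, kind="station", snapped_node=nid)]
    )


def _nearest_node(network: RoadNetwork, target: tuple[float, float]) -> str:
    node_ids = sorted(network.nodes)
    coords = np.array([network.nodes[n] for n in node_ids], dtype=float)
    d2 = (coords[:, 0] - target[0]) ** 2 + (coords[:, 1] - target[1]) ** 2
    return node_ids[int(np.argmin(d2))]
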