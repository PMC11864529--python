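import numpy as np
import pytest

from aedsim.network import Edge, PointSet, RoadNetwork, SitePoint


def make_random_network(
    rng: np.random.Generator,
    n_nodes: int = 30,
    n_extra_edges: int = 40,
    oneway_prob: float = 0.3,
    override_prob: float = 0.1,
) -> RoadNetwork:
    """Random connected-ish test network: a random chain plus extra edges,
    random one-way flags and occasional per-mode speed overrides."""
    ids = [f"n{i:03d}" for i in range(n_nodes)]
    coords = rng.uniform(0, 1000, size=(n_nodes, 2))
    nodes = {ids[i]: (float(coords[i, 0]), float(coords[i, 1])) for i in range(n_nodes)}
    perm = rng.permutation(n_nodes)
    pairs = [(perm[i], perm[i + 1]) for i in range(n_nodes - 1)]
    for _ in range(n_extra_edges):
        u, v = rng.integers(0, n_nodes, size=2)
        if u != v:
            pairs.append((int(u), int(v)))
    edges = []
    for u, v in pairs:
        override = None
        if rng.random() < override_prob:
            override = {"walk": float(rng.uniform(4, 12))}
        edges.append(
            Edge(
                ids[u],
                ids[v],
                length_m=float(rng.uniform(50, 500)),
                oneway=bool(rng.random() < oneway_prob),
                speed_override=override,
            )
        )
    return RoadNetwork(nodes=nodes, edges=edges)


def all_node_pointset(network: RoadNetwork, kind: str = "demand") -> PointSet:
    """One snapped point per network node, in sorted node order."""
    pts = [
        SitePoint(id=f"p_{nid}", x=xy[0], y=xy[1], kind=kind, snapped_node=nid)
        for nid, xy in sorted(network.nodes.items())
    ]
    return PointSet(pts)


@pytest.fixture
def line_network() -> RoadNetwork:
    """Three nodes on a 500 m + 500 m straight line."""
    nodes = {"a": (0.0, 0.0), "b": (500.0, 0.0), "c": (1000.0, 0.0)}
    edges = [Edge("a", "b", 500.0), Edge("b", "c", 500.0)]
    return RoadNetwork(nodes=nodes, edges=edges)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)
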