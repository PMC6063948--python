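"""Spatial network generators based on the nearest-neighbour edge rule.

The basic model scatters ``n`` nodes uniformly in the unit hypercube and
introduces a directed edge ``(n1, n2)`` whenever

    dist(n1, n2) <= rho * min_{m != n1} dist(n1, m)

with ``rho > 1`` controlling the edge density.  Analyses operate on the
associated undirected graph, whose ball volumes grow polynomially with
an exponent close to the dimension of the embedding space.

Hierarchical variants wire each member of a nested family of node sets
``N_l ⊂ ... ⊂ N_0`` independently by the same rule and take the union of
the layer edge sets; a weighted variant assigns each layer-``i`` edge
the Euclidean length of the edge times a per-layer speed factor ``w_i``,
mimicking transport systems whose express layers cover distance more
cheaply.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .graph import SpatialGraph

__all__ = [
    "HierarchySpec",
    "sample_points",
    "mocnik_edges",
    "build_mocnik",
    "build_hierarchical",
    "build_weighted_hierarchical",
]


@dataclass
class HierarchySpec:
    """Parameters of a (weighted) hierarchical spatial network.

    ``layer_sizes`` lists N_0 > N_1 > ... > N_l, strictly decreasing;
    ``rho > 1`` is the density multiplier on the nearest-neighbour
    distance; ``layer_weights`` (optional) gives the per-layer speed
    factors w_0 ... w_l of the weighted variant.
    """

    dim: int
    layer_sizes: tuple
    rho: float
    seed: int
    layer_weights: tuple | None = None

    def __post_init__(self) -> None:
        self.layer_sizes = tuple(int(s) for s in self.layer_sizes)
        if self.dim < 1:
            raise ValueError("dim must be a positive integer")
        if self.rho <= 1:
            raise ValueError("rho must exceed 1")
        if not self.layer_sizes:
            raise ValueError("at least one layer required")
        for a, b in zip(self.layer_sizes, self.layer_sizes[1:]):
            if b >= a:
                raise ValueError("layer sizes must be strictly decreasing")
        if any(s < 2 for s in self.layer_sizes):
            raise ValueError("every layer needs at least 2 nodes")
        if self.layer_weights is not None:
            self.layer_weights = tuple(float(w) for w in self.layer_weights)
            if len(self.layer_weights) != len(self.layer_sizes):
                raise ValueError("layer_weights must match layer_sizes in length")
            if any(w <= 0 for w in self.layer_weights):
                raise ValueError("layer weights must be positive")


def sample_points(n: int, dim: int, seed: int | np.random.Generator) -> np.ndarray:
    """``n`` i.i.d. uniform points in the unit hypercube ``[0,1]^dim``.

    Deterministic given the seed.  Coincident points (probability zero
    under continuous sampling, but possible for adversarial generators)
    are resampled.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if dim < 1:
        raise ValueError("dim must be at least 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    pts = rng.uniform(size=(n, dim))
    # resample exact duplicates (vanishingly rare; guards degenerate draws)
    while True:
        _, idx = np.unique(pts, axis=0, return_index=True)
        if len(idx) == n:
            break
        dup = np.setdiff1d(np.arange(n), idx)
        pts[dup] = rng.uniform(size=(len(dup), dim))
    return pts


def mocnik_edges(points: np.ndarray, rho: float) -> set[tuple[int, int]]:
    """Directed edges of the nearest-neighbour rule on ``points``.

    For each node ``i`` with nearest-neighbour distance ``delta(i)``,
    emits ``(i, j)`` for every ``j != i`` with
    ``dist(i, j) <= rho * delta(i)`` (ties included).  Every node has
    out-degree >= 1, since its nearest neighbour always qualifies.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or len(points) < 2:
        raise ValueError("need at least 2 points in an (n, dim) array")
    if rho <= 1:
        raise ValueError("rho must exceed 1")
    tree = cKDTree(points)
    nn_dist, _ = tree.query(points, k=2)
    delta = nn_dist[:, 1]
    if np.any(delta == 0):
        raise ValueError("coincident points make the edge rule degenerate")
    neighbours = tree.query_ball_point(points, r=rho * delta)
    edges: set[tuple[int, int]] = set()
    for i, nbrs in enumerate(neighbours):
        for j in nbrs:
            if j != i:
                edges.add((i, j))
    return edges


def _undirected_graph(points: np.ndarray, edges, weights: dict | None = None) -> SpatialGraph:
    g = nx.Graph()
    g.add_nodes_from(range(len(points)))
    if weights is None:
        for i, j in edges:
            g.add_edge(i, j, weight=1.0)
        units = "hops"
    else:
        for (i, j), w in weights.items():
            g.add_edge(i, j, weight=w)
        units = "length"
    coords = {i: points[i] for i in range(len(points))}
    return SpatialGraph(g, coords=coords, units=units)


def build_mocnik(n: int, dim: int, rho: float, seed: int) -> SpatialGraph:
    """Single-layer model: sample points, apply the edge rule, symmetrize."""
    pts = sample_points(n, dim, seed)
    edges = mocnik_edges(pts, rho)
    return _undirected_graph(pts, edges)


def _layer_points(spec: HierarchySpec) -> tuple[np.ndarray, list[np.ndarray]]:
    """Base points plus, per layer, the indices (into the base) it contains.

    Each higher layer is a uniform random subset of the layer below,
    drawn from the seeded generator after the base points, so specs that
    share a seed and a layer-size prefix share their lower layers.
    """
    rng = np.random.default_rng(spec.seed)
    pts = sample_points(spec.layer_sizes[0], spec.dim, rng)
    members = [np.arange(spec.layer_sizes[0])]
    for size in spec.layer_sizes[1:]:
        chosen = rng.choice(members[-1], size=size, replace=False)
        members.append(np.sort(chosen))
    return pts, members


def build_hierarchical(spec: HierarchySpec) -> SpatialGraph:
    """Unweighted hierarchical model: union of per-layer edge sets."""
    if spec.layer_weights is not None:
        raise ValueError("use build_weighted_hierarchical for weighted specs")
    pts, members = _layer_points(spec)
    all_edges: set[tuple[int, int]] = set()
    for idx in members:
        layer_edges = mocnik_edges(pts[idx], spec.rho)
        all_edges.update((idx[i], idx[j]) for i, j in layer_edges)
    return _undirected_graph(pts, all_edges)


def build_weighted_hierarchical(spec: HierarchySpec) -> SpatialGraph:
    """Weighted variant: layer-``i`` edges weigh ``w_i`` times their length.

    When the same node pair gains edges in several layers the minimum
    weight survives — a traveller takes the fastest available service.
    """
    if spec.layer_weights is None:
        raise ValueError("spec.layer_weights required for the weighted variant")
    pts, members = _layer_points(spec)
    weights: dict[tuple[int, int], float] = {}
    for idx, w_i in zip(members, spec.layer_weights):
        layer_edges = mocnik_edges(pts[idx], spec.rho)
        for i, j in layer_edges:
            a, b = int(idx[i]), int(idx[j])
            if a > b:
                a, b = b, a
            w = w_i * float(np.linalg.norm(pts[a] - pts[b]))
            key = (a, b)
            if key not in weights or w < weights[key]:
                weights[key] = w
    return _undirected_graph(pts, None, weights=weights)
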