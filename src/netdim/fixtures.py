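"""Deterministic synthetic graphs for testing and comparison runs.

Grid and path fixtures carry natural integer coordinates; trees and
Erdős–Rényi graphs are abstract (no embedding).  All stochastic
fixtures are reproducible from their seed.
"""

from __future__ import annotations

import networkx as nx
import numpy as np

from .graph import SpatialGraph

__all__ = ["make_fixture"]


def make_fixture(kind: str, seed: int = 0, **params) -> SpatialGraph:
    """Build a named fixture graph.

    Kinds and their parameters:

    - ``grid``: ``rows``, ``cols`` — 2D lattice with integer coordinates.
    - ``tree``: ``branching``, ``depth`` — balanced tree, no coordinates.
    - ``erdos_renyi``: ``n``, ``p`` — G(n, p), no coordinates.
    - ``path``: ``n`` — path graph on a line, integer coordinates.
    - ``complete``: ``n`` — complete graph, no coordinates.
    """
    if kind == "grid":
        rows, cols = int(params["rows"]), int(params["cols"])
        if rows < 1 or cols < 1:
            raise ValueError("grid needs rows >= 1 and cols >= 1")
        g0 = nx.grid_2d_graph(rows, cols)
        # integer ids (row-major) so edge lists stay whitespace-clean
        label = {n: n[0] * cols + n[1] for n in g0.nodes()}
        g = nx.Graph()
        g.add_nodes_from(label.values())
        g.add_edges_from((label[u], label[v], {"weight": 1.0}) for u, v in g0.edges())
        coords = {label[n]: np.asarray(n, dtype=float) for n in g0.nodes()}
        return SpatialGraph(g, coords=coords)
    if kind == "tree":
        b, depth = int(params["branching"]), int(params["depth"])
        if b < 1 or depth < 0:
            raise ValueError("tree needs branching >= 1 and depth >= 0")
        g = nx.balanced_tree(b, depth)
        nx.set_edge_attributes(g, 1.0, "weight")
        return SpatialGraph(g)
    if kind == "erdos_renyi":
        n, p = int(params["n"]), float(params["p"])
        if n < 1 or not (0.0 <= p <= 1.0):
            raise ValueError("erdos_renyi needs n >= 1 and p in [0, 1]")
        g = nx.fast_gnp_random_graph(n, p, seed=seed)
        nx.set_edge_attributes(g, 1.0, "weight")
        return SpatialGraph(g)
    if kind == "path":
        n = int(params["n"])
        if n < 1:
            raise ValueError("path needs n >= 1")
        g = nx.path_graph(n)
        nx.set_edge_attributes(g, 1.0, "weight")
        coords = {i: np.asarray([float(i), 0.0]) for i in g.nodes()}
        return SpatialGraph(g, coords=coords)
    if kind == "complete":
        n = int(params["n"])
        if n < 1:
            raise ValueError("complete needs n >= 1")
        g = nx.complete_graph(n)
        nx.set_edge_attributes(g, 1.0, "weight")
        return SpatialGraph(g)
    raise ValueError(f"unknown fixture kind {kind!r}")
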