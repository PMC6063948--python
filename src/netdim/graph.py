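"""Spatial graph data model and plain-text I/O.

The central container is :class:`SpatialGraph`: an undirected, weighted
graph with optional node coordinates in ``R^dim``.  Edge lists are read
and written in the whitespace-separated format used by large public
network repositories (``# comment`` lines, two columns, optional third
weight column); coordinates travel in a sidecar TSV because edge lists
carry none.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import scipy.sparse as sp

__all__ = [
    "SpatialGraph",
    "GraphParseError",
    "read_edge_list",
    "write_graph",
    "read_coords",
    "read_graph",
    "largest_connected_component",
]


class GraphParseError(ValueError):
    """Raised when an edge-list line cannot be parsed."""


@dataclass
class SpatialGraph:
    """Undirected weighted graph with optional spatial embedding.

    Parameters
    ----------
    graph:
        The underlying :class:`networkx.Graph`; every edge carries a
        non-negative ``weight`` attribute (1 for unweighted graphs).
    coords:
        Optional mapping from node id to a coordinate vector.  When
        present, every node must have exactly one vector and all vectors
        share one dimension.
    units:
        Free-form tag recording the unit of the edge weights
        (``"hops"``, ``"minutes"``, length units, ...).
    directed_source:
        Storage-only flag noting that the edges were derived from a
        directed input; all analyses use the undirected graph.
    """

    graph: nx.Graph
    coords: dict | None = None
    units: str = "hops"
    directed_source: bool = False

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants -------------------------------------------------

    def validate(self) -> None:
        g = self.graph
        if any(u == v for u, v in g.edges()):
            raise ValueError("self-loops are not allowed")
        for u, v, w in g.edges(data="weight", default=1.0):
            if w < 0:
                raise ValueError(f"negative weight on edge ({u!r}, {v!r}): {w}")
        if self.coords is not None:
            missing = [n for n in g.nodes() if n not in self.coords]
            if missing:
                raise ValueError(f"nodes without coordinates: {missing[:5]}")
            dims = {np.asarray(self.coords[n]).shape for n in g.nodes()}
            if len(dims) > 1:
                raise ValueError(f"inconsistent coordinate dimensions: {dims}")

    # -- convenience ------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def dim(self) -> int | None:
        if not self.coords:
            return None
        first = next(iter(self.coords.values()))
        return int(np.asarray(first).shape[0])

    def nodes(self) -> list:
        return list(self.graph.nodes())

    def coord_array(self, order: Iterable | None = None) -> np.ndarray:
        """Coordinates stacked into an ``(n, dim)`` array in node order."""
        if self.coords is None:
            raise ValueError("graph has no coordinates")
        if order is None:
            order = self.nodes()
        return np.asarray([self.coords[n] for n in order], dtype=float)

    def to_csr(self, weight: str | None = "weight") -> tuple[sp.csr_matrix, list]:
        """Sparse adjacency matrix plus the node ordering used for rows.

        ``weight=None`` yields a 0/1 adjacency (unweighted traversal).
        """
        order = self.nodes()
        mat = nx.to_scipy_sparse_array(
            self.graph, nodelist=order, weight=weight, format="csr"
        )
        return sp.csr_matrix(mat), order


def _add_collapsed_edge(g: nx.Graph, u, v, w: float, policy: str) -> None:
    # parallel edges collapse; policy decides the surviving weight
    if g.has_edge(u, v):
        old = g[u][v]["weight"]
        if policy == "min":
            g[u][v]["weight"] = min(old, w)
        elif policy == "mean":
            # running mean over occurrences
            cnt = g[u][v].get("_count", 1)
            g[u][v]["weight"] = (old * cnt + w) / (cnt + 1)
            g[u][v]["_count"] = cnt + 1
        else:
            raise ValueError(f"unknown merge policy {policy!r}")
    else:
        g.add_edge(u, v, weight=w)


def read_edge_list(
    path: str | Path, weighted: bool = False, merge: str = "min"
) -> SpatialGraph:
    """Read a whitespace-separated edge list into a :class:`SpatialGraph`.

    Lines starting with ``#`` are comments.  Node ids are kept as opaque
    strings (integer-looking ids are not coerced).  Directed duplicates
    (``a b`` and ``b a``) and repeated pairs collapse to one undirected
    edge; for weighted files the ``merge`` policy (``min`` or ``mean``)
    decides the surviving weight.
    """
    path = Path(path)
    g = nx.Graph()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            need = 3 if weighted else 2
            if len(parts) < need:
                raise GraphParseError(
                    f"{path}:{lineno}: expected {need} fields, got {len(parts)}"
                )
            u, v = parts[0], parts[1]
            if weighted:
                try:
                    w = float(parts[2])
                except ValueError as exc:
                    raise GraphParseError(
                        f"{path}:{lineno}: cannot parse weight {parts[2]!r}"
                    ) from exc
                if w < 0:
                    raise ValueError(f"{path}:{lineno}: negative weight {w}")
            else:
                w = 1.0
            if u == v:
                continue  # drop self-loops on ingest
            _add_collapsed_edge(g, u, v, w, merge)
    for _, _, d in g.edges(data=True):
        d.pop("_count", None)
    return SpatialGraph(g, units="native" if weighted else "hops")


def read_coords(path: str | Path) -> dict:
    """Read a coordinate sidecar TSV (``node_id<TAB>x_1 ... x_dim``).

    Lines holding only a node id (no coordinates) map to ``None``; they
    record isolated nodes of coordinate-free graphs.
    """
    coords: dict = {}
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                coords[parts[0]] = None
            else:
                coords[parts[0]] = np.asarray([float(x) for x in parts[1:]])
    return coords


def read_graph(
    path: str | Path,
    coords_path: str | Path | None = None,
    weighted: bool = True,
    merge: str = "min",
) -> SpatialGraph:
    """Read an edge list plus optional sidecar, restoring isolated nodes."""
    g = read_edge_list(path, weighted=weighted, merge=merge)
    if coords_path is None:
        candidate = Path(path).with_suffix(Path(path).suffix + ".coords.tsv")
        coords_path = candidate if candidate.exists() else None
    if coords_path is not None:
        raw = read_coords(coords_path)
        g.graph.add_nodes_from(raw.keys())
        vectors = {n: v for n, v in raw.items() if v is not None}
        coords = vectors if len(vectors) == len(raw) and vectors else None
        return SpatialGraph(g.graph, coords=coords, units=g.units)
    return g


def write_graph(g: SpatialGraph, path: str | Path, coords_path: str | Path | None = None) -> None:
    """Write ``g`` as an edge list plus, when present, a coordinate sidecar.

    Round-trips through :func:`read_edge_list` / :func:`read_coords` up
    to node-id string normalization.  Isolated nodes appear only in the
    sidecar, so coordinate-free graphs with isolated nodes do not
    round-trip; a sidecar is written for any graph with isolated nodes.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# source target weight\n")
        for u, v, w in g.graph.edges(data="weight", default=1.0):
            fh.write(f"{u} {v} {w!r}\n")
    isolated = [n for n in g.graph.nodes() if g.graph.degree(n) == 0]
    if coords_path is None and (g.coords is not None or isolated):
        coords_path = path.with_suffix(path.suffix + ".coords.tsv")
    if coords_path is not None:
        with Path(coords_path).open("w") as fh:
            for n in g.graph.nodes():
                if g.coords is not None:
                    vec = "\t".join(repr(float(x)) for x in np.asarray(g.coords[n]))
                    fh.write(f"{n}\t{vec}\n")
                else:
                    fh.write(f"{n}\n")


def largest_connected_component(g: SpatialGraph) -> SpatialGraph:
    """Induced subgraph on the largest connected component.

    Ties between equally sized components are broken towards the
    component containing the lexicographically smallest node id
    (comparing ``str(node)``), making the choice deterministic.
    """
    if g.n_nodes == 0:
        raise ValueError("empty graph has no connected component")
    comps = list(nx.connected_components(g.graph))
    comps.sort(key=lambda c: (-len(c), min(str(n) for n in c)))
    keep = comps[0]
    sub = g.graph.subgraph(keep).copy()
    coords = None
    if g.coords is not None:
        coords = {n: g.coords[n] for n in sub.nodes()}
    return SpatialGraph(sub, coords=coords, units=g.units,
                        directed_source=g.directed_source)
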