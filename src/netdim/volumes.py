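"""Ball volumes and volume profiles.

The ball ``B_n(r)`` around a node ``n`` is the set of nodes whose
shortest-path distance from ``n`` (edge count, or summed edge weight)
is at most ``r``; its volume ``|B_n(r)|`` is the number of nodes it
contains, the centre included.  A :class:`VolumeProfile` aggregates
volumes over many sampled centres into per-radius means and standard
deviations — the raw material for fitting volume laws.

All shortest paths are computed with compiled sparse-graph routines;
one single-source sweep per centre yields the volumes at every radius
of the grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy import stats
from scipy.sparse.csgraph import dijkstra

from .graph import SpatialGraph, largest_connected_component

__all__ = ["VolumeProfile", "ball_volume", "volume_profile", "deviation_diagnostics"]

WEIGHT_MODES = ("unweighted", "euclidean", "network_distance", "travel_time", "native")


@dataclass
class VolumeProfile:
    """Per-radius summary of ball volumes over sampled centres."""

    radii: np.ndarray
    mean_volume: np.ndarray
    sd_volume: np.ndarray
    n_samples: int
    network_size: int
    weight_mode: str = "unweighted"
    units: str = "hops"

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        self.mean_volume = np.asarray(self.mean_volume, dtype=float)
        self.sd_volume = np.asarray(self.sd_volume, dtype=float)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "radius": self.radii,
                "mean": self.mean_volume,
                "sd": self.sd_volume,
                "n": self.n_samples,
            }
        )

    @classmethod
    def from_frame(cls, df, network_size: int, weight_mode: str = "native",
                   units: str = "native") -> "VolumeProfile":
        return cls(
            radii=df["radius"].to_numpy(),
            mean_volume=df["mean"].to_numpy(),
            sd_volume=df["sd"].to_numpy(),
            n_samples=int(df["n"].iloc[0]),
            network_size=network_size,
            weight_mode=weight_mode,
            units=units,
        )


def _csr_for_mode(g: SpatialGraph, weight_mode: str) -> tuple[sp.csr_matrix, list, bool]:
    """Adjacency in CSR form with weights rewritten for ``weight_mode``.

    Returns (matrix, node order, unweighted flag).  ``unweighted`` graphs
    traverse by breadth-first search; the other modes run Dijkstra.
    """
    if weight_mode not in WEIGHT_MODES:
        raise ValueError(f"unknown weight mode {weight_mode!r}")
    if weight_mode == "unweighted":
        mat, order = g.to_csr(weight=None)
        return mat, order, True
    if weight_mode == "euclidean":
        if g.coords is None:
            raise ValueError("euclidean weight mode requires coordinates")
        mat, order = g.to_csr(weight=None)
        pts = g.coord_array(order)
        mat = mat.tocoo()
        lengths = np.linalg.norm(pts[mat.row] - pts[mat.col], axis=1)
        mat = sp.csr_matrix((lengths, (mat.row, mat.col)), shape=mat.shape)
        return mat, order, False
    # native / network_distance / travel_time: stored weights
    mat, order = g.to_csr(weight="weight")
    return mat, order, False


def ball_volume(g: SpatialGraph, centre, r: float, weight_mode: str = "native") -> int:
    """Exact number of nodes at shortest-path distance <= ``r`` from ``centre``."""
    if centre not in g.graph:
        raise ValueError(f"unknown centre {centre!r}")
    if r < 0:
        raise ValueError("radius must be non-negative")
    mat, order, unweighted = _csr_for_mode(g, weight_mode)
    idx = order.index(centre)
    dist = dijkstra(mat, directed=False, indices=idx, unweighted=unweighted)
    return int(np.count_nonzero(dist <= r + 1e-12))


def _distances_to_volumes(dist_rows: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """Volumes at every grid radius from raw distance rows (one per centre)."""
    out = np.empty((dist_rows.shape[0], len(radii)), dtype=np.int64)
    shifted = radii + 1e-12  # counts at exact-radius ties included
    for k in range(dist_rows.shape[0]):
        row = np.sort(dist_rows[k])
        out[k] = np.searchsorted(row, shifted, side="right")
    return out


def _sweep(mat, centres_idx, radii, unweighted, chunk=512) -> np.ndarray:
    vols = np.empty((len(centres_idx), len(radii)), dtype=np.int64)
    for lo in range(0, len(centres_idx), chunk):
        idx = centres_idx[lo : lo + chunk]
        dist = dijkstra(mat, directed=False, indices=idx, unweighted=unweighted)
        dist = np.atleast_2d(dist)
        vols[lo : lo + len(idx)] = _distances_to_volumes(dist, radii)
    return vols


def _default_radius_grid(mat, n, rng, unweighted, pilot=200, sat_frac=0.95,
                         n_weighted=64) -> np.ndarray:
    """Data-driven radius grid.

    A pilot sample of centres locates ``r_max``: the radius where the
    mean volume reaches ``sat_frac`` of the network size.  Unweighted
    graphs get the integer grid 0..r_max; weighted graphs a uniform grid
    of ``n_weighted`` values from 0 to r_max.
    """
    pilot_idx = rng.choice(n, size=min(pilot, n), replace=False)
    dist = np.atleast_2d(
        dijkstra(mat, directed=False, indices=pilot_idx, unweighted=unweighted)
    )
    finite = np.where(np.isfinite(dist), dist, 0.0)
    target = sat_frac * n
    # mean volume at r = mean over rows of (#distances <= r)
    flat = np.sort(finite.reshape(-1))
    # pooled count of distances <= r equals (pilot size) x mean volume at r
    k = min(len(flat), int(math.ceil(target * dist.shape[0])))
    r_max = float(flat[k - 1])
    if unweighted:
        r_max = max(int(math.ceil(r_max)), 8)
        return np.arange(0, r_max + 1, dtype=float)
    if r_max <= 0:
        r_max = float(flat[-1]) or 1.0
    return np.linspace(0.0, r_max, n_weighted)


def volume_profile(
    g: SpatialGraph,
    radii: np.ndarray | None = None,
    n_samples: int = 10_000,
    seed: int = 0,
    weight_mode: str = "unweighted",
    centres: list | None = None,
) -> VolumeProfile:
    """Mean and standard deviation of ball volumes over sampled centres.

    Centres are drawn uniformly without replacement from the largest
    connected component (all of it when it is smaller than
    ``n_samples``); one shortest-path sweep per centre yields the
    volumes at every radius of the grid.  ``centres`` overrides the
    sampling with an explicit list of nodes.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be at least 1")
    if radii is not None:
        radii = np.asarray(radii, dtype=float)
        if len(radii) == 0:
            raise ValueError("radius grid must be nonempty")
        if np.any(np.diff(radii) <= 0) or radii[0] < 0:
            raise ValueError("radii must be increasing and non-negative")
    lcc = largest_connected_component(g)
    mat, order, unweighted = _csr_for_mode(lcc, weight_mode)
    n = len(order)
    rng = np.random.default_rng(seed)
    if radii is None:
        radii = _default_radius_grid(mat, n, rng, unweighted)
    if centres is not None:
        pos = {node: i for i, node in enumerate(order)}
        missing = [c for c in centres if c not in pos]
        if missing:
            raise ValueError(f"centres outside the largest component: {missing[:5]}")
        centres_idx = np.asarray([pos[c] for c in centres])
    else:
        centres_idx = rng.choice(n, size=min(n_samples, n), replace=False)
    vols = _sweep(mat, centres_idx, radii, unweighted)
    mean = vols.mean(axis=0)
    sd = vols.std(axis=0, ddof=1) if len(centres_idx) > 1 else np.zeros(len(radii))
    units = {"unweighted": "hops", "euclidean": "length",
             "travel_time": "minutes"}.get(weight_mode, g.units)
    return VolumeProfile(
        radii=radii,
        mean_volume=mean,
        sd_volume=sd,
        n_samples=len(centres_idx),
        network_size=n,
        weight_mode=weight_mode,
        units=units,
    )


@dataclass
class DeviationSummary:
    """Raw per-centre volumes at one radius plus distribution summaries."""

    radius: float
    volumes: np.ndarray
    mean: float
    sd: float | None
    skewness: float | None
    normality_stat: float | None
    normality_p: float | None


def deviation_diagnostics(
    g: SpatialGraph,
    r: float,
    n_samples: int = 10_000,
    seed: int = 0,
    weight_mode: str = "unweighted",
) -> DeviationSummary:
    """Distribution of per-centre volumes at a single radius.

    Provides the material for normality diagnostics (the deviation of
    volumes around the mean is approximately Gaussian for spatial
    models); purely descriptive, no pass/fail semantics.
    """
    lcc = largest_connected_component(g)
    mat, order, unweighted = _csr_for_mode(lcc, weight_mode)
    rng = np.random.default_rng(seed)
    centres_idx = rng.choice(len(order), size=min(n_samples, len(order)), replace=False)
    vols = _sweep(mat, centres_idx, np.asarray([float(r)]), unweighted)[:, 0]
    sd = float(np.std(vols, ddof=1)) if len(vols) > 1 else None
    skew = float(stats.skew(vols)) if len(vols) > 2 and (sd or 0) > 0 else None
    stat = p = None
    if len(vols) >= 20 and (sd or 0) > 0:
        res = stats.normaltest(vols)
        stat, p = float(res.statistic), float(res.pvalue)
    return DeviationSummary(
        radius=float(r),
        volumes=vols,
        mean=float(np.mean(vols)),
        sd=sd,
        skewness=skew,
        normality_stat=stat,
        normality_p=p,
    )
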