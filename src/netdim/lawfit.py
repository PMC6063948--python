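"""Fitting volume profiles with polynomial and exponential volume laws.

The polynomial volume law

    |B(r)| = 1 + k * r^d,    k > 0, d > 0,

links the growth of network ball volumes to the scaling of Euclidean
ball volumes; the fitted exponent ``d`` is the network's dimension.
Networks without a spatial character (sparse random graphs, regular
trees) instead follow an exponential law, modelled here as

    |B(r)| = 1 + a * (b^r - 1),    a > 0, b > 1,

which shares the polynomial law's normalization |B(0)| = 1.

Both laws are fitted by weighted least squares on the natural scale,
weighting each radius by the inverse variance of its mean volume, over
a fit window that excludes the discrete small-radius regime and the
saturated large-radius regime.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .volumes import VolumeProfile

__all__ = [
    "LawFit",
    "FitInfeasibleError",
    "select_window",
    "fit_polynomial",
    "fit_exponential",
    "classify_law",
]


class FitInfeasibleError(ValueError):
    """Raised when no usable fit window exists (e.g. instant saturation)."""


@dataclass
class LawFit:
    """Result of fitting one volume-law family to a profile."""

    family: str                      # "polynomial" | "exponential"
    params: dict                     # k, d | a, b
    std_errors: dict
    window: tuple                    # (r_lo, r_hi) actually used
    rss: float                       # weighted residual sum of squares
    residuals: np.ndarray            # raw (unweighted) residuals, in-window
    n_points: int
    converged: bool = True
    at_bounds: bool = False

    @property
    def dimension(self) -> float | None:
        return self.params.get("d")

    def predict(self, r: np.ndarray) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        if self.family == "polynomial":
            return 1.0 + self.params["k"] * r ** self.params["d"]
        return 1.0 + self.params["a"] * (self.params["b"] ** r - 1.0)


def select_window(
    profile: VolumeProfile,
    min_volume: float = 5.0,
    saturation_fraction: float = 0.5,
    r_lo: float | None = None,
    r_hi: float | None = None,
    min_points: int = 4,
) -> tuple[float, float]:
    """Choose the radius window used for fitting.

    Small radii where the mean volume is below ``min_volume`` are
    dominated by discreteness; radii where it exceeds
    ``saturation_fraction`` of the network size feel the finite-size
    ceiling.  Both ends can be overridden explicitly.
    """
    if len(profile.radii) < 6:
        raise FitInfeasibleError("profile needs at least 6 radii")
    radii, mean = profile.radii, profile.mean_volume
    if r_lo is None:
        ok = mean >= min_volume
        if not ok.any():
            raise FitInfeasibleError("mean volume never reaches the lower threshold")
        r_lo = float(radii[np.argmax(ok)])
    if r_hi is None:
        ok = mean <= saturation_fraction * profile.network_size
        if not ok.any():
            raise FitInfeasibleError("profile saturated at every radius")
        r_hi = float(radii[np.where(ok)[0][-1]])
    mask = (radii >= r_lo) & (radii <= r_hi)
    if mask.sum() < min_points:
        raise FitInfeasibleError(
            f"fit window [{r_lo}, {r_hi}] keeps {int(mask.sum())} points "
            f"(need {min_points}); use a larger network or a finer radius grid"
        )
    return float(r_lo), float(r_hi)


def _window_data(profile: VolumeProfile, window: tuple):
    r_lo, r_hi = window
    mask = (profile.radii >= r_lo) & (profile.radii <= r_hi)
    r = profile.radii[mask]
    y = profile.mean_volume[mask]
    sd = profile.sd_volume[mask].copy()
    pos = sd[sd > 0]
    # deterministic radii (sd 0) get the smallest positive in-window sd
    sd[sd <= 0] = pos.min() if len(pos) else 1.0
    return r, y, sd


def _wls(model, jac, theta0_list, bounds):
    """Weighted least squares with several restarts; best objective wins."""
    best = None
    for theta0 in theta0_list:
        theta0 = np.clip(theta0, bounds[0] + 1e-12, None)
        try:
            res = least_squares(model, theta0, jac=jac, bounds=bounds,
                                method="trf", max_nfev=2000)
        except ValueError:
            continue
        if best is None or res.cost < best.cost:
            best = res
    return best


def _std_errors(res) -> np.ndarray:
    # covariance from the curvature (J^T J) of the weighted objective
    J = res.jac
    try:
        cov = np.linalg.inv(J.T @ J)
        return np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        return np.full(J.shape[1], np.nan)


def _restart_inits(theta0: np.ndarray, n_restarts: int = 5,
                   seed: int = 0) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    inits = [theta0]
    for _ in range(n_restarts - 1):
        inits.append(theta0 * rng.uniform(0.5, 2.0, size=len(theta0)))
    return inits


def fit_polynomial(profile: VolumeProfile, window: tuple | None = None) -> LawFit:
    """Weighted least-squares fit of ``1 + k r^d`` to the profile means.

    Minimizes ``sum_r ((mean[r] - (1 + k r^d)) / sd[r])^2`` over
    ``k, d > 0``; initialized from a log-log regression of ``mean - 1``
    against ``r``, with seeded multiplicative restarts.  Standard errors
    come from the inverse curvature at the optimum.
    """
    if window is None:
        window = select_window(profile)
    r, y, sd = _window_data(profile, window)
    pos = (r > 0) & (y > 1)
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(np.log(r[pos]), np.log(y[pos] - 1.0), 1)
        theta0 = np.asarray([np.exp(intercept), max(slope, 0.05)])
    else:
        theta0 = np.asarray([1.0, 1.0])

    def resid(theta):
        k, d = theta
        return (1.0 + k * r ** d - y) / sd

    def jac(theta):
        k, d = theta
        rd = r ** d
        with np.errstate(divide="ignore"):
            dlog = np.where(r > 0, np.log(r), 0.0)
        return np.column_stack([rd / sd, k * rd * dlog / sd])

    eps = 1e-12
    res = _wls(resid, jac, _restart_inits(theta0), (np.asarray([eps, eps]),
                                                   np.asarray([np.inf, np.inf])))
    if res is None:
        raise FitInfeasibleError("polynomial fit failed to converge")
    k, d = res.x
    se = _std_errors(res)
    return LawFit(
        family="polynomial",
        params={"k": float(k), "d": float(d)},
        std_errors={"k": float(se[0]), "d": float(se[1])},
        window=window,
        rss=float(2 * res.cost),
        residuals=y - (1.0 + k * r ** d),
        n_points=len(r),
        converged=bool(res.success),
        at_bounds=bool(np.any(res.x <= 10 * eps)),
    )


def fit_exponential(profile: VolumeProfile, window: tuple | None = None) -> LawFit:
    """Weighted least-squares fit of ``1 + a (b^r - 1)``, a > 0, b > 1."""
    if window is None:
        window = select_window(profile)
    r, y, sd = _window_data(profile, window)
    pos = y > 1
    if pos.sum() >= 2:
        slope, _ = np.polyfit(r[pos], np.log(y[pos] - 1.0), 1)
        b0 = float(np.exp(max(slope, 1e-3)))
        theta0 = np.asarray([1.0, max(b0, 1.01)])
    else:
        theta0 = np.asarray([1.0, 2.0])

    def resid(theta):
        a, b = theta
        return (1.0 + a * (b ** r - 1.0) - y) / sd

    def jac(theta):
        a, b = theta
        br = b ** r
        return np.column_stack([(br - 1.0) / sd, a * r * br / b / sd])

    lo = np.asarray([1e-12, 1.0 + 1e-9])
    res = _wls(resid, jac, _restart_inits(theta0), (lo, np.asarray([np.inf, np.inf])))
    if res is None:
        raise FitInfeasibleError("exponential fit failed to converge")
    a, b = res.x
    se = _std_errors(res)
    return LawFit(
        family="exponential",
        params={"a": float(a), "b": float(b)},
        std_errors={"a": float(se[0]), "b": float(se[1])},
        window=window,
        rss=float(2 * res.cost),
        residuals=y - (1.0 + a * (b ** r - 1.0)),
        n_points=len(r),
        converged=bool(res.success),
        at_bounds=bool(res.x[1] <= 1.0 + 1e-8),
    )


def _log_rmse(fit: LawFit, profile: VolumeProfile) -> float:
    r, y, _ = _window_data(profile, fit.window)
    pred = fit.predict(r)
    with np.errstate(divide="ignore", invalid="ignore"):
        lr = np.log(np.maximum(pred, 1e-300)) - np.log(np.maximum(y, 1e-300))
    return float(np.sqrt(np.mean(lr ** 2)))


def classify_law(
    profile: VolumeProfile,
    window: tuple | None = None,
    rel_tolerance: float = 0.2,
) -> tuple[str, dict]:
    """Decide which volume law a profile follows.

    Both families are fitted on the same window; the smaller weighted
    RSS wins, unless both fits miss the data by more than
    ``rel_tolerance`` in log-scale RMSE (roughly a 20% relative error),
    in which case the verdict is ``"neither"``.

    Returns ``(verdict, fits)`` with ``fits`` holding whichever
    :class:`LawFit` objects could be computed.
    """
    if window is None:
        window = select_window(profile)
    fits: dict[str, LawFit] = {}
    for name, fitter in (("polynomial", fit_polynomial), ("exponential", fit_exponential)):
        try:
            fits[name] = fitter(profile, window)
        except FitInfeasibleError:
            pass
    if not fits:
        return "neither", fits
    best = min(fits, key=lambda f: fits[f].rss)
    if all(_log_rmse(f, profile) > rel_tolerance for f in fits.values()):
        return "neither", fits
    return best, fits
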