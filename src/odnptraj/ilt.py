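"""Correlation-time spectra by regularized inverse Laplace transform.

A decaying ACF is modelled as a superposition of exponentials,

    g(t) ~= sum_j w_j exp(-t / tau_j),    w_j >= 0,

on a log-spaced grid of correlation times. The weights solve the
Tikhonov-regularized nonnegative least-squares problem

    min_w || A w - g ||^2 + lambda^2 || L w ||^2,   w >= 0,

with L the second-difference (curvature) operator — the standard
CONTIN-style formulation. The regularization parameter can be chosen
automatically at the corner of the L-curve (maximum curvature of
log-residual vs log-seminorm).

Oscillatory ACFs have negative lobes no exponential basis can represent;
only lags before the first zero crossing feed the fit, and the truncation
is recorded in the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .config import RunConfig, TauGridSpec
from .correlate import AcfResult

FS_PER_PS = 1000.0


@dataclass
class CorrelationTimeSpectrum:
    """Nonnegative weights on a log-spaced correlation-time grid (ps)."""

    tau_grid: np.ndarray            # ps, strictly increasing
    weights: np.ndarray             # nonnegative, sum <= 1 + tol
    regularization_lambda: float
    residual_norm: float
    truncated_at_lag: int | None = None
    non_decaying: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def total_mass(self) -> float:
        return float(self.weights.sum())


def make_tau_grid(spec: TauGridSpec) -> np.ndarray:
    return np.logspace(spec.log10_min, spec.log10_max, spec.n_points)


def _design(t_ps: np.ndarray, tau: np.ndarray) -> np.ndarray:
    return np.exp(-np.outer(t_ps, 1.0 / tau))


def _second_difference(m: int) -> np.ndarray:
    L = np.zeros((m - 2, m))
    for i in range(m - 2):
        L[i, i: i + 3] = (1.0, -2.0, 1.0)
    return L


def _truncate_at_zero_crossing(g: np.ndarray) -> int | None:
    neg = np.flatnonzero(g <= 0)
    if neg.size == 0:
        return None
    return int(neg[0])


def _solve_nnls(A: np.ndarray, g: np.ndarray, L: np.ndarray,
                lam: float) -> tuple[np.ndarray, float]:
    if lam > 0:
        A_aug = np.vstack([A, lam * L])
        b_aug = np.concatenate([g, np.zeros(L.shape[0])])
    else:
        A_aug, b_aug = A, g
    w, _ = nnls(A_aug, b_aug)
    resid = float(np.linalg.norm(A @ w - g))
    return w, resid


def choose_lambda(A: np.ndarray, g: np.ndarray, L: np.ndarray,
                  lambdas: np.ndarray | None = None) -> float:
    """L-curve corner: lambda maximizing the curvature of
    (log residual norm, log smoothness seminorm)."""
    if lambdas is None:
        lambdas = np.logspace(-6, 1, 29)
    rho, eta = [], []
    for lam in lambdas:
        w, resid = _solve_nnls(A, g, L, lam)
        rho.append(max(resid, 1e-15))
        eta.append(max(float(np.linalg.norm(L @ w)), 1e-15))
    x = np.log(np.asarray(rho))
    y = np.log(np.asarray(eta))
    # discrete curvature of the parametric curve (x(lam), y(lam))
    dx, dy = np.gradient(x), np.gradient(y)
    ddx, ddy = np.gradient(dx), np.gradient(dy)
    denom = (dx * dx + dy * dy) ** 1.5
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = np.where(denom > 0, (dx * ddy - dy * ddx) / denom, 0.0)
    return float(lambdas[int(np.argmax(kappa))])


def ilt_acf(acf: AcfResult, grid: TauGridSpec | None = None,
            lam: float | str = "auto",
            config: RunConfig | None = None,
            max_rows: int = 600) -> CorrelationTimeSpectrum:
    """Invert an ACF into a distribution of correlation times.

    Parameters
    ----------
    acf
        Must decay: the value at the last used lag has to fall below g[0].
    grid
        Correlation-time grid; defaults to the config's ``tau_grid``
        (60 points/decade over 1e-3..1e2 ps).
    lam
        Regularization parameter, or ``"auto"`` for the L-curve corner.
    max_rows
        The fit subsamples long ACFs to at most this many rows
        (log-spaced lags keep both fast and slow components constrained).
    """
    config = config or RunConfig()
    grid = grid or config.tau_grid
    tau = make_tau_grid(grid)
    g = acf.g.astype(float)
    cut = _truncate_at_zero_crossing(g)
    g_fit = g[:cut] if cut is not None else g
    if g_fit.size < 8:
        raise ValueError("too few positive lags before the first zero "
                         "crossing for an exponential fit")
    if g_fit[-1] >= g_fit[0]:
        raise ValueError("ACF does not decay; inverse Laplace transform "
                         "requires a decaying input")
    t_ps = acf.lags[: g_fit.size] / FS_PER_PS
    if g_fit.size > max_rows:
        # keep lag 0 and log-space the rest
        idx = np.unique(np.concatenate([
            [0], np.geomspace(1, g_fit.size - 1, max_rows - 1).astype(int)
        ]))
        t_ps, g_fit = t_ps[idx], g_fit[idx]
    A = _design(t_ps, tau)
    L = _second_difference(tau.size)
    if lam == "auto":
        lam_val = choose_lambda(A, g_fit, L)
    else:
        lam_val = float(lam)
        if lam_val < 0:
            raise ValueError("lambda must be nonnegative")
    w, resid = _solve_nnls(A, g_fit, L, lam_val)
    non_decaying = bool(np.all(w == 0) and resid > 0.1 * np.linalg.norm(g_fit))
    return CorrelationTimeSpectrum(
        tau_grid=tau, weights=w,
        regularization_lambda=lam_val,
        residual_norm=resid,
        truncated_at_lag=cut,
        non_decaying=non_decaying,
        meta={"channel": acf.channel, "rows": repr(t_ps.size)},
    )


@dataclass
class Component:
    """A resolved correlation-time component: peak position and mass."""

    tau_peak: float    # ps
    mass: float        # integrated weight over the watershed region


def summarize_components(spectrum: CorrelationTimeSpectrum,
                         min_mass: float = 0.01) -> list[Component]:
    """Integrate the weight distribution over watershed regions around each
    local maximum; report components carrying more than ``min_mass`` of the
    total weight, sorted by peak position."""
    w = spectrum.weights
    total = w.sum()
    if total <= 0:
        return []
    peaks = [i for i in range(w.size)
             if w[i] > 0
             and (i == 0 or w[i] >= w[i - 1])
             and (i == w.size - 1 or w[i] > w[i + 1])]
    if not peaks:
        return []
    # watershed boundaries at the minima between consecutive peaks
    bounds = [0]
    for a, b in zip(peaks[:-1], peaks[1:]):
        bounds.append(a + int(np.argmin(w[a:b + 1])))
    bounds.append(w.size)
    out = []
    for k, p in enumerate(peaks):
        lo, hi = bounds[k], bounds[k + 1]
        mass = float(w[lo:hi].sum())
        if mass / total >= min_mass:
            # mass-weighted log-mean within the region is steadier than the
            # raw argmax on a discrete grid
            seg_w = w[lo:hi]
            seg_tau = spectrum.tau_grid[lo:hi]
            tau_peak = float(np.exp(np.sum(seg_w * np.log(seg_tau)) / mass))
            out.append(Component(tau_peak=tau_peak, mass=mass))
    out.sort(key=lambda c: c.tau_peak)
    return out


def resynthesize(spectrum: CorrelationTimeSpectrum,
                 lags_fs: np.ndarray) -> np.ndarray:
    """Forward model: rebuild g(t) from the recovered spectrum."""
    t_ps = np.asarray(lags_fs, float) / FS_PER_PS
    return _design(t_ps, spectrum.tau_grid) @ spectrum.weights
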