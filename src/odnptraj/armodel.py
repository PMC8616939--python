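"""Autoregressive modelling of trajectory channels.

An AR(p) model x_t = phi_1 x_{t-1} + ... + phi_p x_{t-p} + eps_t captures
non-Markovian dynamics with a finite memory of p sampling steps; p * dt is
the memory time in physical units (6 fs for the p = 6 model of spin-density
dynamics at 1 fs sampling). Fits use conditional least squares (the linear
regression of x_t on its p predecessors) with the Gaussian AIC convention

    AIC = n_eff * ln(sigma_hat^2) + 2 (p + 1)

(p coefficients plus the innovation variance; convention recorded in every
result — absolute AIC values are software-specific, only differences and
the argmin are meaningful). Stationarity is verified via the companion-
matrix spectral radius.

Order selection reports both the AIC argmin and a coefficient-convergence
order: the smallest p at which extending the model by one lag moves the
shared coefficients by less than 1% of their aggregate (L1) scale and
leaves the noise level unchanged to the same tolerance. The convergence
order operationalizes "minimal order needed" and is robust to the AIC's
known tendency to admit spurious extra terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trajectory import Trajectory


@dataclass
class ArFit:
    """A fitted AR(p) model for one channel."""

    order: int
    phi: np.ndarray               # phi_1..phi_p
    innovation_variance: float    # au^2
    aic: float
    stationary: bool
    memory_time: float            # p * dt, fs
    n_eff: int
    channel: str = ""
    dt: float = 1.0
    aic_convention: str = "n_eff*ln(sigma2) + 2*(p+1), Gaussian conditional likelihood"
    meta: dict = field(default_factory=dict)


@dataclass
class ArOrderScan:
    """Order scan with AIC table and coefficient-convergence report."""

    fits: list[ArFit]
    aic_table: dict[int, float]
    best_aic_order: int
    converged_order: int | None
    selected_order: int
    convergence_changes: dict[int, float]   # p -> relative coefficient change p->p+1
    arma_comparison: dict | None = None

    @property
    def best(self) -> ArFit:
        return self.fits[self.selected_order]

    @property
    def best_by_aic(self) -> ArFit:
        return self.fits[self.best_aic_order]


def _spectral_radius(phi: np.ndarray) -> float:
    p = phi.size
    if p == 0:
        return 0.0
    comp = np.zeros((p, p))
    comp[0, :] = phi
    if p > 1:
        comp[np.arange(1, p), np.arange(0, p - 1)] = 1.0
    return float(np.max(np.abs(np.linalg.eigvals(comp))))


def fit_ar(traj: Trajectory, channel: str, p: int,
           n_condition: int | None = None, demean: bool = True) -> ArFit:
    """Conditional least-squares AR(p) fit of one channel.

    ``n_condition`` fixes how many initial samples are conditioned on
    (>= p); order scans pass a common value so AIC values are computed on
    the same effective sample and stay comparable across orders.
    """
    x = traj.values(channel).astype(float)
    if demean:
        x = x - x.mean()
    n = x.size
    if p < 0:
        raise ValueError("order must be >= 0")
    if n <= 10 * p:
        raise ValueError(
            f"insufficient data for AR({p}): need n > 10 p, got n = {n}"
        )
    cond = p if n_condition is None else int(n_condition)
    if cond < p:
        raise ValueError("n_condition must be >= p")
    y = x[cond:]
    n_eff = y.size
    if p == 0:
        phi = np.empty(0)
        resid = y
    else:
        X = np.column_stack([x[cond - j: n - j] for j in range(1, p + 1)])
        phi, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ phi
    sigma2 = float(resid @ resid) / n_eff
    if sigma2 <= 0:
        raise ValueError("degenerate fit: zero innovation variance")
    aic = n_eff * np.log(sigma2) + 2.0 * (p + 1)
    return ArFit(
        order=p, phi=np.asarray(phi), innovation_variance=sigma2,
        aic=float(aic), stationary=_spectral_radius(np.asarray(phi)) < 1.0,
        memory_time=p * traj.dt, n_eff=n_eff, channel=channel, dt=traj.dt,
    )


def _coef_change(lo: ArFit, hi: ArFit) -> float:
    """Convergence statistic between the order-p and order-(p+1) fits: the
    largest change of the shared coefficients phi_1..phi_p relative to the
    aggregate coefficient scale (the L1 norm of the larger model), combined
    with the relative change of the innovation variance. The new
    coefficient phi_{p+1} is not shared and does not enter directly; an
    irrelevant extra lag leaves the shared estimates and the noise level
    nearly unchanged, a relevant one shifts them."""
    dvar = (abs(hi.innovation_variance - lo.innovation_variance)
            / lo.innovation_variance)
    if lo.phi.size == 0:
        return float(dvar)
    scale = max(float(np.sum(np.abs(hi.phi))), 1e-300)
    shared = hi.phi[: lo.phi.size]
    coef = float(np.max(np.abs(shared - lo.phi)) / scale)
    return max(coef, float(dvar))


def select_order(traj: Trajectory, channel: str, p_max: int,
                 convergence_tol: float = 0.01,
                 compare_arma: bool = False) -> ArOrderScan:
    """Scan AR orders 0..p_max; report the AIC argmin and the
    coefficient-convergence order.

    ``selected_order`` is the convergence order when one exists (the
    minimal order at which adding a lag no longer moves the coefficients by
    more than ``convergence_tol`` of their largest magnitude), otherwise
    the AIC argmin. Stationarity of the selected fit is verified.
    ``compare_arma=True`` additionally reports the AIC of an ARMA(p,1)
    fit side by side (never selected automatically).
    """
    if p_max < 1:
        raise ValueError("p_max must be >= 1")
    fits = [fit_ar(traj, channel, p, n_condition=p_max)
            for p in range(p_max + 1)]
    aic_table = {f.order: f.aic for f in fits}
    best_aic_order = min(aic_table, key=aic_table.get)
    changes = {p: _coef_change(fits[p], fits[p + 1]) for p in range(p_max)}
    # converged order: first p at which adding a lag leaves the shared
    # coefficients and the noise level unchanged within tol
    converged = None
    for p in range(p_max):
        if changes[p] < convergence_tol:
            converged = p
            break
    selected = converged if converged is not None else best_aic_order
    arma = None
    if compare_arma:
        arma = _arma_comparison(traj, channel, selected if selected > 0 else 1)
    return ArOrderScan(
        fits=fits, aic_table=aic_table, best_aic_order=best_aic_order,
        converged_order=converged, selected_order=selected,
        convergence_changes=changes, arma_comparison=arma,
    )


def _arma_comparison(traj: Trajectory, channel: str, p: int) -> dict:
    """Side-by-side AIC of ARMA(p,1) vs AR(p), reporting only — an MA term
    has no direct physical reading as a time-point correlation."""
    try:
        from statsmodels.tsa.arima.model import ARIMA
    except ImportError:                       # pragma: no cover
        return {"available": False}
    x = traj.values(channel).astype(float)
    x = x - x.mean()
    ar = ARIMA(x, order=(p, 0, 0), trend="n").fit()
    arma = ARIMA(x, order=(p, 0, 1), trend="n").fit()
    return {
        "available": True,
        "order_ar": p,
        "aic_ar": float(ar.aic),
        "aic_arma_p_1": float(arma.aic),
    }


def ljung_box_pvalue(resid: np.ndarray, n_lags: int = 20,
                     n_params: int = 0) -> float:
    """Ljung-Box portmanteau whiteness p-value of fit residuals."""
    from scipy.stats import chi2

    r = np.asarray(resid, float)
    r = r - r.mean()
    n = r.size
    denom = float(r @ r)
    acf = np.array([
        float(r[: n - k] @ r[k:]) / denom for k in range(1, n_lags + 1)
    ])
    q = n * (n + 2.0) * np.sum(acf ** 2 / (n - np.arange(1, n_lags + 1)))
    dof = max(n_lags - n_params, 1)
    return float(chi2.sf(q, dof))


def ar_residuals(traj: Trajectory, channel: str, fit: ArFit) -> np.ndarray:
    """Innovation series of a fitted model on its training channel."""
    x = traj.values(channel).astype(float)
    x = x - x.mean()
    p = fit.order
    y = x[p:]
    if p == 0:
        return y
    X = np.column_stack([x[p - j: x.size - j] for j in range(1, p + 1)])
    return y - X @ fit.phi
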