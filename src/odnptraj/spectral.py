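"""Spectral densities and zero-quantum cross-relaxation estimates.

The spectral density of a fluctuating observable is the one-sided cosine
transform of its ACF,

    J(omega) = 2 * integral_0^infinity g(t) cos(omega t) dt,

so an exponential ACF with correlation time tau gives the Lorentzian
J = 2 tau / (1 + omega^2 tau^2). Scalar ODNP efficiency is governed by J
evaluated at the electron-nucleus zero-quantum (flip-flop) frequency
omega_ZQ = 2 pi (nu_e - nu_n); at 9.4 T the electron-13C ZQ frequency is
0.263 THz (angular 1.65 THz), deep in the sub-ps motional regime.

Conventions are pinned and embedded in every output because they vary
across the literature: one-sided transform with the factor 2 above, J in
ps for a normalized ACF (multiply by the stored variance, au^2, for the
unnormalized variant), and the zero-quantum rate prefactor stated in
:func:`estimate_zq_rate`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .correlate import AcfResult

CONVENTION = "one-sided cosine transform, J(omega) = 2 int_0^inf g(t) cos(omega t) dt"

FS_PER_PS = 1000.0


@dataclass
class SpectralDensity:
    """J(omega) on an angular-frequency grid (rad/ps).

    ``J`` is in ps when normalized, au^2 ps when scaled by the ACF
    variance. Small negative excursions caused by truncating the ACF are
    tolerated and reported via ``min_value``.
    """

    omega: np.ndarray        # rad/ps
    J: np.ndarray            # ps or au^2 ps
    normalized: bool
    convention: str = CONVENTION
    windowing: str = "none"
    variance: float = 1.0    # au^2, the scale factor when unnormalized
    meta: dict = field(default_factory=dict)

    @property
    def min_value(self) -> float:
        return float(self.J.min())

    def at(self, omega: float) -> float:
        """Linear interpolation of J at an angular frequency (rad/ps)."""
        if not self.omega[0] <= omega <= self.omega[-1]:
            raise ValueError(
                f"omega {omega:g} rad/ps outside grid "
                f"[{self.omega[0]:g}, {self.omega[-1]:g}]"
            )
        return float(np.interp(omega, self.omega, self.J))


@dataclass(frozen=True)
class ZqParams:
    """Field parameters for the electron-nucleus zero-quantum transition.

    ``nu_e``/``nu_c``: electron and 13C Larmor frequencies in GHz;
    ``a_iso``: isotropic hyperfine (Fermi-contact) coupling in MHz.
    """

    nu_e: float
    nu_c: float
    a_iso: float = 0.0

    def __post_init__(self) -> None:
        if not self.nu_e > self.nu_c >= 0:
            raise ValueError("need nu_e > nu_c >= 0")
        if self.a_iso < 0:
            raise ValueError("a_iso must be nonnegative")


def acf_to_spectral_density(acf: AcfResult, normalized: bool = True,
                            omega: np.ndarray | None = None,
                            window: str = "none") -> SpectralDensity:
    """One-sided cosine transform of an ACF.

    Discrete transform with trapezoid end-correction (half weights at the
    first and last lag); the default grid spans 0 to pi/dt (the lag-grid
    Nyquist angular frequency) with one point per resolved frequency.
    ``window="cosine"`` applies a half-cosine taper for noisy ACFs and is
    recorded in the output.
    """
    t_ps = acf.lags / FS_PER_PS
    dt_ps = acf.dt / FS_PER_PS
    g = acf.g.astype(float).copy()
    if window == "cosine":
        g = g * np.cos(0.5 * np.pi * np.arange(g.size) / (g.size - 1)) ** 2
    elif window != "none":
        raise ValueError(f"unknown window {window!r}")
    if omega is None:
        # one point per resolved frequency, capped to keep the dense
        # cosine matrix modest; J is smooth on this grid
        n = min(g.size, 4096)
        omega = np.linspace(0.0, np.pi / dt_ps, n)
    omega = np.asarray(omega, float)
    w = np.ones_like(g)
    w[0] = w[-1] = 0.5
    wg = w * g
    # J(w_k) = 2 dt sum_j w_j g_j cos(w_k t_j), chunked over frequencies
    J = np.empty(omega.size)
    chunk = max(1, int(4e6 // max(t_ps.size, 1)))
    for i in range(0, omega.size, chunk):
        J[i:i + chunk] = np.cos(np.outer(omega[i:i + chunk], t_ps)) @ wg
    J *= 2.0 * dt_ps
    if not normalized:
        J = J * acf.variance
    return SpectralDensity(
        omega=omega, J=J, normalized=normalized,
        windowing="applied" if window != "none" else "none",
        variance=acf.variance,
        meta={"channel": acf.channel, "n_lags": repr(acf.n_lags)},
    )


def zq_frequency(params: ZqParams) -> float:
    """Electron-nucleus zero-quantum angular frequency, rad/ps.

    omega_ZQ = 2 pi (nu_e - nu_c); divide by 2 pi for the linear frequency
    (e.g. 263 GHz electron / 100.6 MHz carbon give ~0.263 THz linear,
    ~1.65 THz angular).
    """
    delta_ghz = params.nu_e - params.nu_c
    return 2.0 * np.pi * delta_ghz * 1e-3     # GHz -> cycles/ps -> rad/ps


def zq_frequency_thz(params: ZqParams) -> tuple[float, float]:
    """(linear THz, angular THz) of the zero-quantum transition."""
    w = zq_frequency(params)
    return w / (2.0 * np.pi), w


RATE_CONVENTION = ("R_ZQ = 1/4 * (2 pi a_iso)^2 * J(omega_ZQ), "
                   "a_iso in Hz, J in s (convention-dependent)")


def estimate_zq_rate(J_at_zq: float, params: ZqParams) -> dict:
    """Zero-quantum cross-relaxation rate from the spectral density.

    ``J_at_zq`` must be in seconds (a J in ps divides by 1e12). The
    prefactor 1/4 (2 pi a_iso)^2 is this package's declared scalar-coupling
    convention, embedded in the output; different spectral-density
    normalizations rescale the absolute rate but not its ordering across
    sites.
    """
    a_hz = params.a_iso * 1e6
    clamped = False
    J = float(J_at_zq)
    if J < 0:
        import warnings

        warnings.warn("negative spectral density clamped to 0 for the rate "
                      "estimate", stacklevel=2)
        J, clamped = 0.0, True
    rate = 0.25 * (2.0 * np.pi * a_hz) ** 2 * J
    return {
        "rate_per_s": float(rate),
        "convention": RATE_CONVENTION,
        "clamped_negative_J": clamped,
    }


def parseval_mismatch(acf: AcfResult, sd: SpectralDensity) -> float:
    """Relative Parseval mismatch |int J domega / pi - g(0) * scale| / scale.

    For the one-sided convention, integral_0^inf J(omega) domega / pi equals
    the lag-0 autocovariance; small mismatch validates transform and grid.
    """
    scale = sd.variance if not sd.normalized else 1.0
    total = float(np.trapezoid(sd.J, sd.omega)) / np.pi
    return abs(total - acf.g[0] * scale) / abs(scale)
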