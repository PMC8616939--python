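"""Run configuration shared by all pipeline stages.

The defaults reproduce the analysis conditions used throughout: ACFs are
truncated at half the trajectory duration, the memory-kernel recursion runs
at 100 decimal digits, and channels are mean-centered before correlation.
Every result file echoes the full configuration so any output can be traced
back to the parameters that produced it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass(frozen=True)
class TauGridSpec:
    """Log-spaced correlation-time grid for the inverse Laplace transform.

    Spans ``10**log10_min`` .. ``10**log10_max`` ps with ``points_per_decade``
    grid points per decade.
    """

    log10_min: float = -3.0
    log10_max: float = 2.0
    points_per_decade: int = 60

    def __post_init__(self) -> None:
        if self.log10_max <= self.log10_min:
            raise ValueError("tau grid must span a positive range")
        if self.points_per_decade < 2:
            raise ValueError("need at least 2 points per decade")

    @property
    def n_points(self) -> int:
        decades = self.log10_max - self.log10_min
        return int(round(decades * self.points_per_decade)) + 1


@dataclass(frozen=True)
class RunConfig:
    precision_digits: int = 100
    max_lag_fraction: float = 0.5
    centering: str = "mean"        # {"mean", "none"}
    tau_grid: TauGridSpec = field(default_factory=TauGridSpec)
    ilt_regularization: float = 1e-3
    ar_max_order: int = 12
    # memory-kernel convolution quadrature: the product-trapezoid
    # (Stieltjes) rule telescopes exactly for constant kernels; the
    # end-corrected Gregory trapezoid is kept for comparison
    quadrature: str = "product_trapezoid"   # {"product_trapezoid", "gregory"}
    seed: int = 0

    def __post_init__(self) -> None:
        if self.precision_digits < 1:
            raise ValueError("precision_digits must be a positive integer")
        if not 0.0 < self.max_lag_fraction <= 0.5:
            raise ValueError("max_lag_fraction must lie in (0, 0.5]")
        if self.centering not in ("mean", "none"):
            raise ValueError("centering must be 'mean' or 'none'")
        if self.ilt_regularization < 0:
            raise ValueError("ilt_regularization must be nonnegative")
        if self.ar_max_order < 1:
            raise ValueError("ar_max_order must be positive")
        if self.quadrature not in ("product_trapezoid", "gregory"):
            raise ValueError(
                "quadrature must be 'product_trapezoid' or 'gregory'"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        return d
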