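"""Shared paths and loaders for the analysis scripts."""

from pathlib import Path

import numpy as np

from odnptraj.correlate import AcfResult
from odnptraj.io import read_result

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"


def load_acf(name: str, max_lags: int | None = None) -> AcfResult:
    """Reload an ACF result written by 02, optionally truncating lags."""
    r = read_result(SCRATCH / "acf" / f"{name}.json")["result"]
    n = len(r["g"]) if max_lags is None else min(max_lags, len(r["g"]))
    return AcfResult(
        lags=np.asarray(r["lags"][:n], float),
        g=np.asarray(r["g"][:n], float),
        variance=float(r["variance"]),
        n_points_used=int(r["n_points_used"]),
        centering=r["centering"],
        channel=r.get("channel", ""),
        dt=float(r["dt"]),
    )
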