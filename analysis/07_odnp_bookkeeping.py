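#!/usr/bin/env python
"""Enhancement factors, paramagnetic shifts, lifetimes and volumes.

Runs the NMR-side bookkeeping on synthetic measurement tables: the
Overhauser enhancement with propagated error, molar-free paramagnetic
shifts from a noisy titration (0-200 mM radical), complex lifetimes in
the H-bond and halogen-bond binding regimes, and the active sample
volumes of the capillary resonator geometries.
"""

import json
import sys
from pathlib import Path

from odnptraj.odnp import (
    CONSTANTS, LifetimeParams, TitrationSeries, capillary_volume,
    complex_lifetime, enhancement, molar_free_shift,
)
from odnptraj.synth import gen_titration

sys.path.insert(0, str(Path(__file__).parent))
from _common import RESULTS

SEED = 20240907

def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rec = enhancement(I_dnp=51.0, I_boltz=1.0, n_dnp=8, n_boltz=8,
                      snr_dnp=120.0, snr_boltz=15.0)
    print(f"enhancement: epsilon = {rec.epsilon:.1f} +/- "
          f"{rec.delta_epsilon:.2f}")

    conc = [0.0, 0.05, 0.10, 0.15, 0.20]      # M, the 0-200 mM window
    df = gen_titration(slope=5.0, intercept=120.0, conc_list=conc,
                       noise_sd=0.02, seed=SEED, label="C2")
    res = molar_free_shift(TitrationSeries.from_frame(df))
    print(f"titration:   delta_para_bar(C2) = {res.delta_para_bar['C2']:.3f} "
          f"+/- {res.fit_error['C2']:.3f} ppm/M (truth 5.0)")

    tau_h = complex_lifetime(LifetimeParams(K_a=1.0, k_on=1e10))
    tau_x = complex_lifetime(LifetimeParams(K_a=1e-2, k_on=1e10))
    print(f"lifetimes:   H-bond regime {tau_h:.0f} ps, halogen-bond regime "
          f"{tau_x:.1f} ps")

    v100 = capillary_volume(100, 4.5)
    v50 = capillary_volume(50, 4.5)
    print(f"volumes:     {v100['volume_nl_rounded']} nL (100 um), "
          f"{v50['volume_nl_rounded']} nL (50 um)")
    print(f"gyromagnetic ratios: gamma_e/gamma_H = "
          f"{CONSTANTS.gamma_e_over_h1:.0f}, gamma_e/gamma_C = "
          f"{CONSTANTS.gamma_e_over_c13:.0f}")

    out = {
        "enhancement": {"epsilon": rec.epsilon,
                        "delta_epsilon": rec.delta_epsilon},
        "titration": {"delta_para_bar": res.delta_para_bar,
                      "fit_error": res.fit_error},
        "lifetime_ps": {"hbond_Ka_1": tau_h, "halogen_Ka_0.01": tau_x},
        "volumes_nl": {"d100um": v100, "d50um": v50},
        "gamma_ratios": {"e_over_h1": CONSTANTS.gamma_e_over_h1,
                         "e_over_c13": CONSTANTS.gamma_e_over_c13},
    }
    (RESULTS / "07_odnp.json").write_text(json.dumps(out, indent=2))

if __name__ == "__main__":
    main()
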