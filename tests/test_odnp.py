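"""Enhancement factors, paramagnetic shifts, lifetimes, volumes, constants."""

import numpy as np
import pytest

from odnptraj.odnp import (
    CONSTANTS,
    LifetimeParams,
    TitrationSeries,
    capillary_volume,
    complex_lifetime,
    enhancement,
    molar_free_shift,
)
from odnptraj.synth import gen_titration


class TestEnhancement:
    def test_null_enhancement(self):
        rec = enhancement(3.0, 3.0, 8, 8, 100, 100)
        assert rec.epsilon == 0.0

    def test_fifty_fold(self):
        rec = enhancement(51.0, 1.0, 4, 4, 120, 15)
        assert rec.epsilon == 50.0

    def test_negative_enhancement_sign_convention(self):
        rec = enhancement(-10.0, 1.0, 4, 4, 50, 10)
        assert rec.epsilon == -11.0

    def test_scan_count_ratio(self):
        rec = enhancement(10.0, 1.0, 16, 4, 50, 10)
        assert rec.epsilon == pytest.approx(10.0 * (4 / 16) - 1)

    def test_invariant_under_common_integral_rescale(self):
        a = enhancement(51.0, 1.0, 4, 4, 120, 15)
        b = enhancement(5.1, 0.1, 4, 4, 120, 15)
        assert a.epsilon == pytest.approx(b.epsilon)

    def test_zero_reference_rejected(self):
        with pytest.raises(ZeroDivisionError):
            enhancement(1.0, 0.0, 1, 1, 10, 10)

    def test_bad_snr_rejected(self):
        with pytest.raises(ValueError, match="signal-to-noise"):
            enhancement(1.0, 1.0, 1, 1, -5, 10)

    @pytest.mark.parametrize("I_dnp,I_boltz,snr_d,snr_b", [
        (1.0, 1.0, 100.0, 100.0),    # epsilon = 0 case
        (51.0, 1.0, 120.0, 15.0),
        (10.0, 2.0, 40.0, 12.0),
    ])
    def test_delta_epsilon_matches_monte_carlo(self, I_dnp, I_boltz,
                                               snr_d, snr_b):
        rec = enhancement(I_dnp, I_boltz, 8, 8, snr_d, snr_b)
        rng = np.random.default_rng(123)
        n = 200_000
        i_d = I_dnp + rng.standard_normal(n) / snr_d
        i_b = I_boltz + rng.standard_normal(n) / snr_b
        eps = i_d / i_b - 1.0
        mc_sd = eps.std(ddof=1)
        assert abs(rec.delta_epsilon - mc_sd) / mc_sd < 0.05


class TestMolarFreeShift:
    def test_exact_line(self):
        s = TitrationSeries(radical_conc=[0.0, 0.1, 0.2],
                            shifts={"C1": [1.0, 1.2, 1.4]})
        res = molar_free_shift(s)
        assert res.delta_para_bar["C1"] == pytest.approx(2.0)
        assert res.fit_error["C1"] == pytest.approx(0.0, abs=1e-10)

    def test_concentration_independent_shift_zero_slope(self):
        s = TitrationSeries(radical_conc=[0.0, 0.05, 0.1, 0.2],
                            shifts={"C1": [7.0, 7.0, 7.0, 7.0]})
        assert molar_free_shift(s).delta_para_bar["C1"] == pytest.approx(0.0)

    def test_identical_concentrations_rejected(self):
        s = TitrationSeries(radical_conc=[0.1, 0.1, 0.1],
                            shifts={"C1": [1.0, 2.0, 3.0]})
        with pytest.raises(np.linalg.LinAlgError):
            molar_free_shift(s)

    def test_estimator_unbiased_over_seeds(self):
        # 100 replicates: the mean recovered slope sits within 3 SE of truth
        slope, noise = 5.0, 0.02
        conc = [0.0, 0.05, 0.1, 0.15, 0.2]
        ests = []
        for seed in range(100):
            df = gen_titration(slope, 0.0, conc, noise_sd=noise, seed=seed)
            res = molar_free_shift(TitrationSeries.from_frame(df))
            ests.append(res.delta_para_bar["C"])
        mean = np.mean(ests)
        se_mean = np.std(ests, ddof=1) / 10.0
        assert abs(mean - slope) < 3 * se_mean

    def test_overlap_sd_reported(self):
        df = gen_titration(5.0, 0.0, [0.0, 0.05, 0.1, 0.2], 0.01, seed=1,
                           label="C3")
        df["shift_ppm:C5"] = gen_titration(5.2, 0.0, [0.0, 0.05, 0.1, 0.2],
                                           0.01, seed=2)["shift_ppm:C"]
        res = molar_free_shift(TitrationSeries.from_frame(df),
                               overlap=("C3", "C5"))
        expected = np.std([res.delta_para_bar["C3"],
                           res.delta_para_bar["C5"]], ddof=1)
        assert res.overlap_sd == pytest.approx(expected)


class TestLifetime:
    def test_hbond_regime_100_ps(self):
        assert complex_lifetime(LifetimeParams(K_a=1.0, k_on=1e10)) == 100.0

    def test_halogen_regime_1_ps(self):
        assert complex_lifetime(LifetimeParams(K_a=1e-2, k_on=1e10)) == pytest.approx(1.0)

    def test_linear_in_ka(self):
        base = complex_lifetime(LifetimeParams(K_a=0.3, k_on=1e10))
        assert complex_lifetime(LifetimeParams(K_a=0.6, k_on=1e10)) == pytest.approx(2 * base)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            LifetimeParams(K_a=0.0)


class TestVolumesAndConstants:
    def test_capillary_volumes_match_cavity_report(self):
        assert capillary_volume(100, 4.5)["volume_nl_rounded"] == 35
        assert capillary_volume(50, 4.5)["volume_nl_rounded"] == 9

    def test_zero_length(self):
        assert capillary_volume(100, 0.0)["volume_nl"] == 0.0

    def test_gyromagnetic_ratio_integers(self):
        assert round(CONSTANTS.gamma_e_over_h1) == -658
        assert round(CONSTANTS.gamma_e_over_c13) == -2617
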