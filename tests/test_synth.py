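"""Statistical fidelity of the synthetic-trajectory generators."""

import numpy as np
import pytest

from odnptraj.config import RunConfig
from odnptraj.correlate import compute_acf
from odnptraj.synth import (
    ArSpec,
    DampedOscSpec,
    DefaultConditions,
    OuSpec,
    PulseModelSpec,
    ar6_reference_spec,
    gen_ar,
    gen_damped_osc,
    gen_ou,
    gen_pulse_model,
    gen_titration,
)


def batch_acf_se(x: np.ndarray, lag: int, n_batches: int = 50) -> float:
    """Standard error of the lag-k sample autocorrelation by batch means."""
    m = x.size // n_batches
    vals = []
    for b in range(n_batches):
        seg = x[b * m:(b + 1) * m]
        seg = seg - seg.mean()
        vals.append(float(seg[:-lag] @ seg[lag:]) / float(seg @ seg))
    return float(np.std(vals, ddof=1) / np.sqrt(n_batches))


class TestOu:
    def test_zero_noise_is_constant_at_mean(self):
        traj = gen_ou(OuSpec(tau_c=0.1, sigma=0.0, mean=2.5), n=200, seed=1)
        np.testing.assert_allclose(traj.values("ou"), 2.5)

    def test_acf_matches_closed_form_at_one_tau(self):
        tau_ps = 0.1
        traj = gen_ou(OuSpec(tau_c=tau_ps, sigma=1.0), n=100_000, dt=1.0, seed=7)
        x = traj.values("ou")
        lag = 100                       # 0.1 ps at 1 fs sampling
        acf = compute_acf(traj, "ou")
        se = batch_acf_se(x, lag)
        assert abs(acf.g[lag] - np.exp(-1.0)) < 3 * se

    def test_seed_determinism(self):
        a = gen_ou(OuSpec(tau_c=0.05), n=500, seed=42)
        b = gen_ou(OuSpec(tau_c=0.05), n=500, seed=42)
        np.testing.assert_array_equal(a.values("ou"), b.values("ou"))

    def test_invalid_tau_rejected(self):
        with pytest.raises(ValueError, match="tau_c"):
            OuSpec(tau_c=-1.0)


class TestPulseModel:
    def test_zero_amplitude_is_identically_zero(self):
        spec = PulseModelSpec(encounter_rate=1.0, mean_duration=0.1,
                              amplitude=0.0)
        traj = gen_pulse_model(spec, n=1000, seed=3)
        assert np.all(traj.values("pulse") == 0.0)

    def test_on_fraction_matches_renewal_theory(self):
        spec = PulseModelSpec(encounter_rate=1.0, mean_duration=0.1,
                              amplitude=1.0)
        n = 1_000_000
        traj = gen_pulse_model(spec, n=n, dt=1.0, seed=5)
        x = traj.values("pulse")
        frac = x.mean()
        expected = 1.0 / 11.0           # rate*dur/(1+rate*dur)
        # batch-means SE over 100 segments of the 0/1 indicator
        m = n // 100
        seg_means = x[: 100 * m].reshape(100, m).mean(axis=1)
        se = seg_means.std(ddof=1) / 10.0
        assert abs(frac - expected) < 3 * se

    def test_acf_decays_on_mixing_time_scale(self):
        spec = PulseModelSpec(encounter_rate=1.0, mean_duration=0.1,
                              amplitude=1.0)
        traj = gen_pulse_model(spec, n=1_000_000, dt=1.0, seed=9)
        cfg = RunConfig(max_lag_fraction=0.001)
        acf = compute_acf(traj, "pulse", cfg)
        # telegraph-process ACF is exp(-t/t_mix); fit a single exponential
        lags_ps = acf.lags / 1000.0
        keep = (acf.g > 0.05) & (lags_ps > 0)
        slope = np.polyfit(lags_ps[keep], np.log(acf.g[keep]), 1)[0]
        tau_fit = -1.0 / slope
        assert abs(tau_fit - spec.mixing_time) / spec.mixing_time < 0.30


class TestAr:
    def test_phi_zero_is_white_noise(self):
        traj = gen_ar(ArSpec(phi=(0.0,)), n=20_000, seed=2)
        acf = compute_acf(traj, "ar")
        assert abs(acf.g[1]) < 3.0 / np.sqrt(20_000)

    def test_ar1_lag1_autocorrelation(self):
        traj = gen_ar(ArSpec(phi=(0.9,)), n=100_000, seed=8)
        acf = compute_acf(traj, "ar")
        se = batch_acf_se(traj.values("ar"), 1)
        assert abs(acf.g[1] - 0.9) < 3 * se

    def test_nonstationary_spec_rejected_with_radius(self):
        with pytest.raises(ValueError, match="spectral radius"):
            ArSpec(phi=(1.01,))

    def test_reference_spec_is_stationary_order_six(self):
        spec = ar6_reference_spec()
        assert spec.order == 6
        assert spec.spectral_radius < 1.0


class TestDampedOsc:
    def test_single_zero_frequency_component_matches_ou(self):
        tau = 0.1
        spec = DampedOscSpec(components=((tau, 0.0, 1.0),))
        traj = gen_damped_osc(spec, n=100_000, seed=4)
        acf = compute_acf(traj, "dosc")
        se = batch_acf_se(traj.values("dosc"), 100)
        assert abs(acf.g[100] - np.exp(-1.0)) < 3 * se

    def test_negative_lobe_near_half_period(self):
        # decay 0.05 ps with a 0.3 ps wave: the theoretical ACF
        # e^{-t/0.05} cos(2 pi t/0.3) turns negative at the quarter period
        # (75 fs) and its first minimum sits near the half period (150 fs)
        spec = DampedOscSpec(components=((0.05, 2 * np.pi / 0.3, 1.0),))
        traj = gen_damped_osc(spec, n=200_000, seed=6)
        cfg = RunConfig(max_lag_fraction=0.002)
        acf = compute_acf(traj, "dosc", cfg)
        first_neg = np.flatnonzero(acf.g < 0)[0]
        assert 50 < first_neg < 110        # theory: 75 fs
        lobe = np.argmin(acf.g[:300])
        assert 110 < lobe < 200            # theory: ~150 fs
        assert acf.g[lobe] < 0

    def test_sample_acf_tracks_theoretical_acf(self):
        cond = DefaultConditions()
        spec = cond.damped_osc_spec()
        traj = gen_damped_osc(spec, n=200_000, seed=10)
        cfg = RunConfig(max_lag_fraction=0.005)
        acf = compute_acf(traj, "dosc", cfg)
        theory = spec.theoretical_acf(acf.lags / 1000.0)
        assert np.max(np.abs(acf.g - theory)) < 0.05

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            DampedOscSpec(components=((0.1, 0.0, 0.5), (0.2, 0.0, 0.6)))


class TestTitration:
    def test_zero_noise_exact_line(self):
        df = gen_titration(slope=2.0, intercept=1.0,
                           conc_list=[0.0, 0.1, 0.2], noise_sd=0.0)
        np.testing.assert_allclose(df["shift_ppm:C"], [1.0, 1.2, 1.4])

    def test_slope_recovery_within_fit_se(self):
        from odnptraj.odnp import TitrationSeries, molar_free_shift

        df = gen_titration(slope=5.0, intercept=0.0,
                           conc_list=[0.0, 0.05, 0.1, 0.2], noise_sd=0.01,
                           seed=13)
        res = molar_free_shift(TitrationSeries.from_frame(df))
        assert abs(res.delta_para_bar["C"] - 5.0) < 3 * res.fit_error["C"]

    def test_zero_slope_estimate_consistent_with_zero(self):
        from odnptraj.odnp import TitrationSeries, molar_free_shift

        # 9 concentrations keep the t-distributed slope/SE ratio well behaved
        df = gen_titration(slope=0.0, intercept=3.0,
                           conc_list=np.linspace(0.0, 0.2, 9), noise_sd=0.01,
                           seed=14)
        res = molar_free_shift(TitrationSeries.from_frame(df))
        assert abs(res.delta_para_bar["C"]) < 3 * res.fit_error["C"]
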