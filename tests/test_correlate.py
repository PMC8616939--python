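"""Autocorrelation and covariance estimators."""

import numpy as np
import pytest

from odnptraj.config import RunConfig
from odnptraj.correlate import compute_acf, compute_covariance
from odnptraj.synth import ArSpec, OuSpec, gen_ar, gen_ou
from odnptraj.trajectory import Trajectory


def traj_from(x, dt=1.0, name="x"):
    return Trajectory.from_arrays(np.arange(len(x)) * dt, {name: np.asarray(x, float)})


def test_alternating_series_gives_alternating_acf():
    x = np.tile([1.0, -1.0], 50)
    acf = compute_acf(traj_from(x), "x")
    expected = (-1.0) ** np.arange(acf.n_lags)
    np.testing.assert_allclose(acf.g, expected, atol=1e-12)


def test_normalization_and_truncation():
    rng = np.random.default_rng(0)
    n = 1000
    acf = compute_acf(traj_from(rng.standard_normal(n)), "x")
    assert acf.g[0] == 1.0
    assert acf.n_lags == n // 2 + 1
    assert np.all(np.abs(acf.g) <= 1 + 1e-9)


def test_ou_acf_within_three_se_of_closed_form():
    traj = gen_ou(OuSpec(tau_c=0.1, sigma=1.0), n=100_000, dt=1.0, seed=7)
    acf = compute_acf(traj, "ou")
    x = traj.values("ou")
    lag = 100
    nb, m = 50, x.size // 50
    per_batch = []
    for b in range(nb):
        seg = x[b * m:(b + 1) * m] - x[b * m:(b + 1) * m].mean()
        per_batch.append(float(seg[:-lag] @ seg[lag:]) / float(seg @ seg))
    se = np.std(per_batch, ddof=1) / np.sqrt(nb)
    assert abs(acf.g[lag] - np.exp(-1)) < 3 * se


def test_time_reversal_leaves_acf_unchanged():
    rng = np.random.default_rng(3)
    x = np.cumsum(rng.standard_normal(512)) * 0.1 + rng.standard_normal(512)
    fwd = compute_acf(traj_from(x), "x")
    rev = compute_acf(traj_from(x[::-1]), "x")
    np.testing.assert_allclose(fwd.g, rev.g, rtol=0, atol=1e-12)


def test_white_noise_band():
    n = 50_000
    traj = gen_ar(ArSpec(phi=()), n=n, seed=21)
    acf = compute_acf(traj, "ar")
    # the per-lag estimator averages N-k products, so its null SD is
    # 1/sqrt(N-k), widening toward the half-length truncation
    counts = n - np.arange(1, acf.n_lags)
    band = 3.0 / np.sqrt(counts)
    frac_out = np.mean(np.abs(acf.g[1:]) > band)
    assert frac_out < 0.01


def test_fsum_and_fft_paths_agree_to_12_digits():
    rng = np.random.default_rng(5)
    traj = traj_from(rng.standard_normal(4000))
    a = compute_acf(traj, "x", method="fft")
    b = compute_acf(traj, "x", method="fsum")
    # agreement in significant digits on a normalized scale
    assert np.max(np.abs(a.g - b.g)) < 1e-12


def test_constant_series_zero_variance_error():
    with pytest.raises(ZeroDivisionError, match="zero variance"):
        compute_acf(traj_from(np.full(100, 3.0)), "x")


def test_missing_channel_lookup_error(small_traj):
    with pytest.raises(KeyError, match="no channel"):
        compute_acf(small_traj, "nope")


def test_uncentered_acf_of_offset_series_plateaus():
    rng = np.random.default_rng(9)
    x = 5.0 + 0.1 * rng.standard_normal(20_000)
    cfg = RunConfig(centering="none")
    acf = compute_acf(traj_from(x), "x", cfg)
    # mean dominates: uncentered ACF stays near 1 instead of decaying
    assert acf.g[-1] > 0.99
    assert acf.centering == "none"


class TestCovariance:
    def test_diagonal_is_variance(self, small_traj):
        cov = compute_covariance(small_traj, ["C2", "C3"])
        x = small_traj.values("C2")
        assert cov.matrix[0, 0] == pytest.approx(np.var(x, ddof=1))

    def test_sign_flip_gives_negative_variance(self):
        rng = np.random.default_rng(17)
        x = rng.standard_normal(500)
        traj = Trajectory.from_arrays(np.arange(500.0), {"x": x, "y": -x})
        cov = compute_covariance(traj, ["x", "y"])
        assert cov.matrix[0, 1] == pytest.approx(-np.var(x, ddof=1))
        assert cov.negative_entries()[0][:2] == ("x", "y")

    def test_independent_channels_nearly_uncorrelated(self):
        n = 100_000
        a = gen_ou(OuSpec(tau_c=0.05), n=n, seed=1).values("ou")
        b = gen_ou(OuSpec(tau_c=0.05), n=n, seed=2).values("ou")
        traj = Trajectory.from_arrays(np.arange(float(n)), {"a": a, "b": b})
        cov = compute_covariance(traj)
        r = cov.matrix[0, 1] / np.sqrt(cov.matrix[0, 0] * cov.matrix[1, 1])
        # OU samples are autocorrelated (tau = 50 steps); the null SE of the
        # cross-correlation widens by ~sqrt(2 tau / dt)
        assert abs(r) < 3 * np.sqrt(2 * 50.0 / n)

    def test_symmetry_enforced(self, small_traj):
        cov = compute_covariance(small_traj)
        np.testing.assert_allclose(cov.matrix, cov.matrix.T, atol=1e-15)

    def test_needs_two_channels(self, small_traj):
        with pytest.raises(ValueError, match="at least 2"):
            compute_covariance(small_traj, ["C2"])
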