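import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from spinedyn import (
    FitError,
    delta_vs_w_profile,
    fit_decay_time_constant,
    fit_lognormal,
    fit_normal,
    pearson_r,
    percent_daily_change,
    weight_histogram,
    yasumatsu_c1,
)

from .oracles import pearson_ref


class TestWeightHistogram:
    def test_counts_conserved(self, rng):
        w = rng.lognormal(0.0, 1.0, size=10_000)
        hist = weight_histogram(w)
        assert hist.counts.sum() == 10_000
        assert np.all(np.diff(hist.bin_edges) > 0)

    def test_active_scope_filters(self, rng):
        w = np.concatenate([np.full(50, 0.05), rng.lognormal(0, 1, 150)])
        active = np.concatenate([np.zeros(50, bool), np.ones(150, bool)])
        hist = weight_histogram(w, active=active, scope="active-only")
        assert hist.counts.sum() == 150

    def test_all_equal_weights_single_bin(self):
        hist = weight_histogram(np.full(100, 2.0))
        assert (hist.counts > 0).sum() == 1
        assert hist.counts.sum() == 100

    def test_nonpositive_weights_rejected(self):
        with pytest.raises(ValueError):
            weight_histogram(np.array([1.0, 0.0]))

    @given(st.integers(min_value=5, max_value=120))
    def test_conservation_for_any_binning(self, n_bins):
        rng = np.random.default_rng(0)
        w = rng.lognormal(0, 1, 500)
        assert weight_histogram(w, n_bins=n_bins).counts.sum() == 500


class TestDistributionFits:
    def test_lognormal_parameter_recovery(self):
        rng = np.random.default_rng(1)
        mu, sigma, n = 0.0131, 0.9341, 10_000
        fit = fit_lognormal(rng.lognormal(mu, sigma, n))
        assert fit.params["mu"] == pytest.approx(mu, abs=3 * sigma / np.sqrt(n))
        assert fit.params["sigma"] == pytest.approx(sigma, abs=3 * sigma / np.sqrt(2 * n))

    def test_lognormal_histogram_method_close_to_mle_on_clean_sample(self):
        rng = np.random.default_rng(2)
        w = rng.lognormal(0.5, 0.8, 20_000)
        mle = fit_lognormal(w, method="mle")
        hist = fit_lognormal(w, method="histogram")
        assert hist.params["sigma"] == pytest.approx(mle.params["sigma"], rel=0.05)

    def test_lognormal_rejects_bad_input(self):
        with pytest.raises(FitError):
            fit_lognormal(np.array([1.0, -1.0] * 10))
        with pytest.raises(FitError):
            fit_lognormal(np.full(100, 3.0))  # zero spread
        with pytest.raises(FitError):
            fit_lognormal(np.array([1.0, 2.0]))  # too few

    def test_normal_recovery_and_symmetry(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0.0, 0.07, 50_000)
        fit = fit_normal(x)
        assert fit.params["mean"] == pytest.approx(0.0, abs=4 * 0.07 / np.sqrt(50_000))
        assert fit.params["sd"] == pytest.approx(0.07, rel=0.02)

    def test_normal_histogram_fit_ignores_central_spike(self):
        rng = np.random.default_rng(4)
        broad = rng.normal(0.0, 0.07, 40_000)
        spike = rng.normal(0.0, 0.004, 8_000)
        fit = fit_normal(np.concatenate([broad, spike]), method="histogram",
                         exclude_epsilon=0.01)
        assert fit.params["sd"] == pytest.approx(0.07, abs=0.01)

    def test_parameter_recovery_over_replicates(self):
        """MLE recovery within 3 standard errors in ~99% of replicates."""
        rng = np.random.default_rng(5)
        n = 2_000
        failures_sigma = failures_sd = 0
        for _ in range(100):
            w = rng.lognormal(0.2, 0.9, n)
            se = 0.9 / np.sqrt(2 * n)
            if abs(fit_lognormal(w).params["sigma"] - 0.9) > 3 * se:
                failures_sigma += 1
            x = rng.normal(0.0, 0.07, n)
            se = 0.07 / np.sqrt(2 * n)
            if abs(fit_normal(x).params["sd"] - 0.07) > 3 * se:
                failures_sd += 1
        assert failures_sigma <= 3
        assert failures_sd <= 3


class TestPercentDailyChange:
    def test_zero_changes(self):
        assert percent_daily_change(np.ones(5), np.zeros(5)) == 0.0

    def test_single_synapse_arithmetic(self):
        assert percent_daily_change([1.0], [0.165]) == pytest.approx(16.5)

    def test_rejects_nonpositive_weights(self):
        with pytest.raises(ValueError):
            percent_daily_change([0.0], [0.1])


class TestDeltaProfile:
    def test_constant_delta_flat_profile(self, rng):
        w = rng.lognormal(0, 1, 5_000)
        prof = delta_vs_w_profile(w, np.full(5_000, 0.05), n_bins=20)
        assert np.allclose(prof["mean_dw"], 0.05)
        assert np.allclose(prof["mean_abs_dw"], 0.05)

    def test_relative_change_decreases_for_weight_proportional_noise(self, rng):
        # |dW| growing sublinearly in W implies decreasing relative change
        w = rng.lognormal(0, 1, 20_000)
        d = np.sqrt(w) * rng.normal(0, 0.1, 20_000)
        prof = delta_vs_w_profile(w, d, n_bins=15)
        rel = prof["mean_rel_abs_dw"].to_numpy()
        assert rel[0] > rel[-1]


class TestPearson:
    def test_identity_and_anticorrelation(self):
        assert pearson_r([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
        assert pearson_r([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_matches_hand_computed_value(self):
        x, y = [1.0, 2.0, 3.0, 4.0], [2.0, 4.0, 5.0, 9.0]
        assert pearson_r(x, y) == pytest.approx(pearson_ref(x, y), rel=1e-12)

    def test_affine_invariance_and_symmetry(self, rng):
        x = rng.normal(size=100)
        y = rng.normal(size=100)
        r = pearson_r(x, y)
        assert pearson_r(3.0 * x + 1.0, y) == pytest.approx(r, rel=1e-9)
        assert pearson_r(y, x) == pytest.approx(r, rel=1e-9)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestDecayFit:
    def test_recovers_known_time_constant(self):
        t = np.arange(0, 1500, 10)
        fit = fit_decay_time_constant(t, np.exp(-t / 500.0))
        assert fit.params["tau"] == pytest.approx(500.0, rel=1e-6)

    def test_offset_form_recovery(self):
        t = np.arange(0, 1500, 10)
        r = 0.2 + 0.8 * np.exp(-t / 400.0)
        fit = fit_decay_time_constant(t, r, with_offset=True)
        assert fit.params["tau"] == pytest.approx(400.0, rel=1e-4)
        assert fit.params["offset"] == pytest.approx(0.2, abs=1e-6)

    def test_constant_series_fails(self):
        with pytest.raises(FitError):
            fit_decay_time_constant(np.arange(20), np.ones(20))

    def test_noisy_recovery_within_tolerance(self):
        rng = np.random.default_rng(6)
        t = np.arange(0, 1500, 10)
        r = np.exp(-t / 500.0) + rng.normal(0, 0.01, t.size)
        fit = fit_decay_time_constant(t, r)
        assert fit.params["tau"] == pytest.approx(500.0, rel=0.05)


class TestYasumatsuC1:
    @pytest.mark.parametrize(
        "v, expected",
        [(0.6, 0.0), (0.1, -0.006), (0.5, 0.0), (0.25, -0.03), (0.0, 0.01)],
    )
    def test_piecewise_values(self, v, expected):
        assert yasumatsu_c1(v) == pytest.approx(expected, abs=1e-12)

    def test_continuity_at_branch_boundaries(self):
        for b in (0.25, 0.5):
            below = yasumatsu_c1(b - 1e-9)
            above = yasumatsu_c1(b + 1e-9)
            assert abs(below - above) < 1e-6

    def test_negative_volume_rejected(self):
        with pytest.raises(ValueError):
            yasumatsu_c1(-0.1)
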