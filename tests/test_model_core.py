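import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from spinedyn import (
    ClusterState,
    ModelParams,
    draw_increment,
    ltd_amplitude,
    ltp_amplitude,
    ltp_mean_amplitude,
    regeneration_probability,
    step_cluster,
    volatility,
)
from spinedyn.model_core import draw_day_randoms

from .oracles import cluster_day_ref


class TestVolatility:
    @pytest.mark.parametrize(
        "w, expected",
        [
            (0.0, 4.0),                  # upper bound at zero weight
            (0.4, 2.1),                  # midway between bounds at W_med
            (1.0, 4.0 - 3.8 * (1.0 / 1.4)),
        ],
    )
    def test_reference_values(self, params, w, expected):
        assert volatility(w, params) == pytest.approx(expected, rel=1e-12)

    def test_strictly_decreasing_on_grid(self, params):
        grid = np.linspace(0.0, 100.0, 2001)
        values = volatility(grid, params)
        assert np.all(np.diff(values) < 0)
        assert np.all(values > params.v_lo)
        assert values[0] == params.v_hi

    def test_negative_weight_rejected(self, params):
        with pytest.raises(ValueError):
            volatility(-0.1, params)


class TestLtpMeanAmplitude:
    @pytest.mark.parametrize("n_st, expected", [(0, 0.18), (10, 0.144), (5, 0.162)])
    def test_linear_interpolation(self, params, n_st, expected):
        assert ltp_mean_amplitude(n_st, params) == pytest.approx(expected)

    def test_out_of_range_rejected(self, params):
        with pytest.raises(ValueError):
            ltp_mean_amplitude(11, params)
        with pytest.raises(ValueError):
            ltp_mean_amplitude(-1, params)

    @given(st.integers(min_value=0, max_value=10))
    def test_bounded_and_nonincreasing(self, n_st):
        p = ModelParams()
        a1 = ltp_mean_amplitude(n_st, p)
        assert p.x1 <= a1 <= p.x2
        if n_st < p.N_cl:
            assert ltp_mean_amplitude(n_st + 1, p) <= a1

    def test_fixed_variant_ignores_cluster_state(self):
        p = ModelParams(variant="fixed_ltp")
        assert ltp_mean_amplitude(0, p) == ltp_mean_amplitude(10, p) == p.a1_fixed


class TestAmplitudes:
    def test_ltp_amplitude_reference_value(self, params):
        # direct evaluation: 0.18 * VO(1) * (1 - 0.05/21)
        expected = 1.0 * 0.18 * (4.0 - 3.8 / 1.4) * (1.0 - 0.05 * 1.0 / 21.0)
        assert ltp_amplitude(1.0, 0.18, params) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.2308775, abs=1e-6)

    def test_ltd_amplitude_reference_value(self, params):
        assert ltd_amplitude(1.0, 0.16, params) == pytest.approx(
            0.16 * (4.0 - 3.8 / 1.4), rel=1e-12
        )

    @pytest.mark.parametrize("func", [ltp_amplitude, ltd_amplitude])
    def test_zero_weight_or_increment_gives_zero(self, params, func):
        assert func(0.0, 0.5, params) == 0.0
        assert func(2.0, 0.0, params) == 0.0

    def test_saturation_limit_at_large_weight(self, params):
        # bracket tends to 1 - k_hi for very large weights
        w = 1e9
        bracket = ltp_amplitude(w, 1.0, params) / ltd_amplitude(w, 1.0, params)
        assert bracket == pytest.approx(1.0 - params.k_hi, rel=1e-6)

    def test_negative_inputs_rejected(self, params):
        with pytest.raises(ValueError):
            ltp_amplitude(-1.0, 0.1, params)
        with pytest.raises(ValueError):
            ltd_amplitude(1.0, -0.1, params)


class TestRegenerationProbability:
    @pytest.mark.parametrize("n_st, expected", [(0, 0.0), (5, 0.05), (10, 0.1)])
    def test_linear_in_strong_count(self, params, n_st, expected):
        assert regeneration_probability(n_st, params) == pytest.approx(expected)

    def test_no_regeneration_variant_is_zero(self):
        p = ModelParams(variant="no_regeneration")
        assert regeneration_probability(10, p) == 0.0

    def test_out_of_range_rejected(self, params):
        with pytest.raises(ValueError):
            regeneration_probability(11, params)


class TestDrawIncrement:
    def test_gaussian_mean_and_nonnegativity(self, params, rng):
        draws = draw_increment(0.16, params, rng, size=1_000_000)
        assert np.all(draws >= 0)
        se = (0.16 / 4) / math.sqrt(draws.size)
        assert abs(draws.mean() - 0.16) < 4 * se

    def test_exponential_variant_mean(self, rng):
        p = ModelParams(variant="exponential_increments", lambda1=2.0)
        draws = draw_increment(0.16, p, rng, kind="ltp", size=1_000_000)
        assert np.all(draws >= 0)
        assert draws.mean() == pytest.approx(0.5, rel=0.01)

    def test_nonpositive_mean_rejected(self, params, rng):
        with pytest.raises(ValueError):
            draw_increment(0.0, params, rng)


class TestStepCluster:
    def test_all_silent_cluster_unchanged(self, params, rng):
        cluster = ClusterState(
            weights=np.full(10, params.W_sil), active=np.zeros(10, dtype=bool)
        )
        out = step_cluster(cluster, params, rng)
        np.testing.assert_array_equal(out.weights, cluster.weights)
        assert not out.active.any()

    def test_zero_increments_leave_weights_unchanged(self, params):
        weights = np.full(10, 5.0)
        cluster = ClusterState(weights=weights, active=np.ones(10, dtype=bool))
        # raw draws that map to r1 = r2 = 0 after clamping
        e = np.full(10, -100.0)
        out = step_cluster(cluster, params, draws=(e, e, np.zeros(10)))
        np.testing.assert_array_equal(out.weights, weights)
        assert out.active.all()

    def test_silencing_resets_to_basal_weight(self, params):
        weights = np.full(10, 0.09)
        cluster = ClusterState(weights=weights, active=np.ones(10, dtype=bool))
        # enormous LTD draw drives every weight below the threshold
        e1 = np.full(10, -100.0)
        e2 = np.full(10, 100.0)
        out = step_cluster(cluster, params, draws=(e1, e2, np.ones(10)))
        np.testing.assert_array_equal(out.weights, np.full(10, params.W_sil))
        assert not out.active.any()

    def test_regeneration_requires_strong_neighbour(self, params):
        # synapse 0 silent next to a strong synapse; synapse 9 silent with a
        # weak neighbour: only synapse 0 may regenerate
        weights = np.array([params.W_sil, 5.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 0.3,
                            params.W_sil])
        active = np.array([False] + [True] * 8 + [False])
        cluster = ClusterState(weights=weights, active=active)
        zero = np.full(10, -100.0)  # no weight change
        out = step_cluster(cluster, params, draws=(zero, zero, np.zeros(10)))
        assert out.active[0]
        assert out.weights[0] == params.W_reset
        assert not out.active[9]
        assert out.weights[9] == params.W_sil

    def test_same_day_silencing_does_not_regenerate(self, params):
        # a synapse silenced today is not eligible for regeneration today
        weights = np.array([0.09] + [5.0] * 9)
        active = np.ones(10, dtype=bool)
        e1 = np.full(10, -100.0)
        e2 = np.concatenate([[100.0], np.full(9, -100.0)])
        out = step_cluster(
            ClusterState(weights, active), params, draws=(e1, e2, np.zeros(10))
        )
        assert not out.active[0]
        assert out.weights[0] == params.W_sil

    @pytest.mark.parametrize("variant", ["standard", "fixed_ltp",
                                         "no_regeneration",
                                         "exponential_increments"])
    def test_matches_independent_reference_loop(self, variant, rng):
        p = ModelParams(variant=variant)
        weights = rng.uniform(0.1, 3.0, size=10)
        active = rng.random(10) > 0.3
        weights[~active] = p.W_sil
        cluster = ClusterState(weights.copy(), active.copy())
        for _ in range(50):
            e1, e2, u = draw_day_randoms(p, rng, (10,))
            out = step_cluster(cluster, p, draws=(e1, e2, u))
            ref_w, ref_a, _ = cluster_day_ref(
                list(cluster.weights), list(cluster.active), p,
                list(e1), list(e2), list(u),
            )
            # independent coding: agree to float round-off, not bit order
            np.testing.assert_allclose(out.weights, np.array(ref_w), rtol=1e-12)
            np.testing.assert_array_equal(out.active, np.array(ref_a))
            cluster = out

    def test_counts_conserved_and_silent_exact(self, params, rng):
        cluster = ClusterState.uniform(params)
        for _ in range(500):
            cluster = step_cluster(cluster, params, rng)
            assert cluster.n_cl == params.N_cl
            assert np.all(cluster.weights >= 0)
            silent = ~cluster.active
            np.testing.assert_array_equal(
                cluster.weights[silent], np.full(silent.sum(), params.W_sil)
            )
            assert np.all(cluster.weights[cluster.active] >= params.T_wk)
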