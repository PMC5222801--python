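"""Learning windows, online accumulators vs brute-force oracles, drift."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from modplast.errors import ConfigurationError, NormalizationError
from modplast.plasticity import (
    LearningWindow,
    TripletParams,
    WeightTrajectory,
    apply_bounds,
    brute_force_pair_sum,
    brute_force_triplet_sum,
    expected_drift,
    learning_window,
    normalize_weights,
    online_pair_accumulation,
    online_triplet_accumulation,
    window_value,
)

RULES = ("DP", "PP", "UP", "DU")


def random_trains(seed, n_pre=20, n_post=20, duration=1.0):
    rng = np.random.default_rng(seed)
    grid = np.arange(0.0, duration, 1e-4)
    pre = np.sort(rng.choice(grid, size=n_pre, replace=False))
    post = np.sort(rng.choice(grid, size=n_post, replace=False))
    return pre, post


class TestWindowValue:
    def test_up_has_no_acausal_branch(self):
        assert window_value(learning_window("UP"), -0.010) == 0.0

    def test_du_has_no_causal_branch(self):
        assert window_value(learning_window("DU"), +0.010) == 0.0

    def test_causal_exponential_value(self):
        w = LearningWindow("DP", a_causal=0.01, a_acausal=-0.01, tau_causal=0.020)
        assert window_value(w, 0.010) == pytest.approx(0.01 * math.exp(-0.5), rel=1e-12)

    def test_zero_lag_contributes_nothing(self):
        for rid in RULES:
            assert window_value(learning_window(rid), 0.0) == 0.0

    def test_alpha_scales_window(self):
        w = learning_window("DP", alpha=2.0)
        assert window_value(w, 0.005) == 2.0 * window_value(w.with_alpha(1.0), 0.005)

    @pytest.mark.parametrize("rid,a_c,a_ac", [("DP", 1.0, 1.0), ("UP", -1.0, 0.0)])
    def test_sign_constraints_enforced(self, rid, a_c, a_ac):
        with pytest.raises(ConfigurationError):
            LearningWindow(rid, a_causal=a_c, a_acausal=a_ac)


class TestPairOracle:
    def test_empty_trains_give_zero(self):
        w = learning_window("DP")
        assert brute_force_pair_sum([], [], w) == 0.0
        assert online_pair_accumulation([], [], w) == 0.0

    def test_single_pair_equals_window_value(self):
        w = learning_window("DP")
        assert brute_force_pair_sum([0.0], [0.010], w) == window_value(w, 0.010)
        assert online_pair_accumulation([0.0], [0.010], w) == pytest.approx(
            window_value(w, 0.010), rel=1e-14
        )

    @pytest.mark.parametrize("rid", RULES)
    def test_online_matches_brute_force(self, rid):
        w = learning_window(rid, alpha=0.3)
        for seed in range(10):
            pre, post = random_trains(seed)
            bf = brute_force_pair_sum(pre, post, w)
            on = online_pair_accumulation(pre, post, w)
            assert on == pytest.approx(bf, rel=1e-12, abs=1e-14)

    def test_simultaneous_events_excluded_both_paths(self):
        w = learning_window("PP")
        pre = np.array([0.1, 0.2])
        post = np.array([0.2, 0.3])
        bf = brute_force_pair_sum(pre, post, w)
        on = online_pair_accumulation(pre, post, w)
        assert on == pytest.approx(bf, rel=1e-12)
        # the (0.2, 0.2) pair contributes zero
        expected = sum(
            window_value(w, q - p) for p in pre for q in post if q != p
        )
        assert bf == pytest.approx(expected, rel=1e-12)

    def test_alpha_zero_freezes(self):
        pre, post = random_trains(3)
        assert online_pair_accumulation(pre, post, learning_window("PP", alpha=0.0)) == 0.0


class TestTriplet:
    def params(self, a3c=0.05, a3ac=-0.04):
        return TripletParams(
            learning_window("DP", alpha=0.3), a3_causal=a3c, a3_acausal=a3ac
        )

    def test_no_spikes_no_change(self):
        assert online_triplet_accumulation([], [], self.params()) == 0.0

    def test_zero_triplet_amplitudes_reduce_to_pair_rule(self):
        for seed in range(5):
            pre, post = random_trains(seed)
            w = learning_window("DP", alpha=0.3)
            trip = online_triplet_accumulation(pre, post, TripletParams(w))
            pair = online_pair_accumulation(pre, post, w)
            assert trip == pair  # bit-identical: same code path, zero added terms

    def test_matches_exhaustive_enumeration(self):
        for seed in range(8):
            pre, post = random_trains(seed, n_pre=15, n_post=15)
            p = self.params()
            bf = brute_force_triplet_sum(pre, post, p)
            on = online_triplet_accumulation(pre, post, p)
            assert on == pytest.approx(bf, rel=1e-12, abs=1e-14)

    def test_invalid_time_constants_rejected(self):
        with pytest.raises(ConfigurationError):
            TripletParams(learning_window("DP"), tau_x=0.0)


class TestBoundsAndNormalization:
    def test_in_range_unchanged(self):
        w = np.array([1.0, 5.0, 9.0])
        np.testing.assert_array_equal(apply_bounds(w, 0.0, 10.0), w)

    def test_clipping_and_idempotence(self):
        w = np.array([-1.0, 5.0, 12.0])
        c = apply_bounds(w, 0.0, 10.0)
        np.testing.assert_array_equal(c, [0.0, 5.0, 10.0])
        np.testing.assert_array_equal(apply_bounds(c, 0.0, 10.0), c)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ConfigurationError):
            apply_bounds(np.ones(3), 5.0, 5.0)

    def test_multiplicative_rescaling(self):
        np.testing.assert_allclose(
            normalize_weights(np.array([1.0, 3.0]), 2.0), [0.5, 1.5]
        )

    def test_target_sum_achieved_when_unclipped(self):
        rng = np.random.default_rng(0)
        w = rng.uniform(0.1, 5.0, 8)
        assert normalize_weights(w, 12.0).sum() == pytest.approx(12.0)

    def test_already_normalized_unchanged(self):
        w = np.array([0.5, 1.5])
        np.testing.assert_allclose(normalize_weights(w, 2.0), w)

    def test_all_zero_vector_raises(self):
        with pytest.raises(NormalizationError):
            normalize_weights(np.zeros(4), 1.0)

    def test_trajectory_rejects_out_of_bound_weights(self):
        with pytest.raises(ConfigurationError):
            WeightTrajectory(
                times=[0.0], weights=np.array([[11.0]]), w_min=0.0, w_max=10.0
            )


class TestExpectedDrift:
    def test_balanced_dp_drifts_at_zero(self):
        assert expected_drift(10.0, 10.0, learning_window("DP")) == pytest.approx(0.0)

    def test_depression_excess_gives_negative_drift(self):
        w = learning_window("DP", alpha=0.01, depression_excess=0.02)
        assert expected_drift(10.0, 10.0, w) < 0

    def test_matches_monte_carlo_for_independent_trains(self):
        # frozen-weight accumulation on independent Poisson trains
        w = learning_window("PP", alpha=0.01)
        pred = expected_drift(10.0, 10.0, w)
        rng = np.random.default_rng(5)
        T, n = 20.0, 100
        vals = []
        for _ in range(n):
            pre = np.sort(rng.uniform(0, T, rng.poisson(10 * T)))
            post = np.sort(rng.uniform(0, T, rng.poisson(10 * T)))
            vals.append(online_pair_accumulation(pre, post, w) / T)
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / np.sqrt(n)
        assert abs(vals.mean() - pred) < 3 * se


@given(st.integers(0, 10_000))
@settings(max_examples=25, deadline=None)
def test_window_antisymmetric_dp_property(seed):
    """Balanced DP window is antisymmetric: W(dt) = -W(-dt)."""
    rng = np.random.default_rng(seed)
    dt = rng.uniform(1e-4, 0.1)
    w = learning_window("DP")
    assert window_value(w, dt) == pytest.approx(-window_value(w, -dt), rel=1e-12)
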