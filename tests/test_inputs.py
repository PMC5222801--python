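"""Correlated Poisson input generator: statistics, locality, determinism."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from modplast.errors import ConfigurationError
from modplast.inputs import (
    InputEnsembleConfig,
    apply_training_boost,
    generate_ensemble,
    generate_signals,
    mix_signals,
    sample_poisson_spikes,
    training_gain_vector,
    _mixing_kernel,
)


def cfg(**kw):
    base = dict(n_inputs=10, base_rate=10.0)
    base.update(kw)
    return InputEnsembleConfig(**base)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(n_inputs=0),
            dict(base_rate=-1.0),
            dict(training_gain=-0.5),
            dict(boundary_mode="mirror"),
            dict(training_index=11),
            dict(training_index=0),
            dict(dt=0.0),
            dict(signal_dt=2.5e-4),  # not an integer multiple of dt
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ConfigurationError):
            cfg(**kw)


class TestSignals:
    def test_zero_base_rate_gives_zero_signals(self):
        s = generate_signals(cfg(base_rate=0.0), 1.0, 0)
        assert np.all(s == 0.0)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_signals(cfg(), 0.0, 0)

    def test_fixed_seed_reproducible(self):
        a = generate_signals(cfg(), 2.0, 7)
        b = generate_signals(cfg(), 2.0, 7)
        np.testing.assert_array_equal(a, b)

    def test_signals_nonnegative_and_near_base_rate(self):
        s = generate_signals(cfg(), 50.0, 1)
        assert np.all(s >= 0.0)
        assert np.allclose(s.mean(axis=1), 10.0, atol=1.5)

    def test_channels_uncorrelated(self):
        s = generate_signals(cfg(n_inputs=2), 200.0, 3)
        r = np.corrcoef(s[0], s[1])[0, 1]
        assert abs(r) < 0.05

    def test_autocorrelation_timescale(self):
        # OU signals decorrelate on signal_timescale: r(lag=tau) ~ 1/e
        c = cfg(n_inputs=1, signal_timescale=0.05)
        s = generate_signals(c, 200.0, 11)[0]
        lag = int(round(0.05 / c.signal_dt))
        r = np.corrcoef(s[:-lag], s[lag:])[0, 1]
        assert 0.2 < r < 0.55


class TestMixing:
    def test_zero_width_is_identity(self):
        c = cfg(mixing_width=0.0)
        s = generate_signals(c, 1.0, 0)
        np.testing.assert_array_equal(mix_signals(s, c), s)

    def test_constant_signals_conserved(self):
        c = cfg()
        s = np.full((10, 100), 10.0)
        np.testing.assert_allclose(mix_signals(s, c), 10.0)

    def test_negative_signals_rejected(self):
        with pytest.raises(ConfigurationError):
            mix_signals(-np.ones((10, 5)), cfg())

    @given(
        n=st.integers(2, 30),
        width=st.floats(0.1, 5.0),
        wrap=st.booleans(),
    )
    @settings(max_examples=40, deadline=None)
    def test_kernel_rows_normalized_nonnegative(self, n, width, wrap):
        c = cfg(
            n_inputs=n,
            mixing_width=width,
            boundary_mode="wrap" if wrap else "clip",
        )
        k = _mixing_kernel(c)
        assert np.all(k >= 0)
        np.testing.assert_allclose(k.sum(axis=1), 1.0, atol=1e-12)

    def test_neighbor_correlation_exceeds_distant(self):
        # averaged over seeds: corr decays with index distance
        c = cfg(n_inputs=8)
        r_near, r_far = [], []
        for seed in range(20):
            rates = mix_signals(generate_signals(c, 20.0, seed), c)
            r_near.append(np.corrcoef(rates[3], rates[4])[0, 1])
            r_far.append(np.corrcoef(rates[2], rates[7])[0, 1])
        assert np.mean(r_near) > np.mean(r_far) + 0.2

    def test_correlation_monotone_in_distance(self):
        c = cfg(n_inputs=8)
        acc = np.zeros(4)
        for seed in range(20):
            rates = mix_signals(generate_signals(c, 20.0, seed), c)
            for d in range(1, 5):
                acc[d - 1] += np.corrcoef(rates[1], rates[1 + d])[0, 1]
        acc /= 20
        assert np.all(np.diff(acc) < 0.05)  # non-increasing up to noise


class TestTrainingBoost:
    def test_unit_gain_is_identity(self):
        c = cfg(training_index=4, training_gain=1.0)
        rates = mix_signals(generate_signals(c, 5.0, 0), c)
        np.testing.assert_array_equal(apply_training_boost(rates, c), rates)

    def test_doubles_training_trace_leaves_distant_untouched(self):
        c = cfg(training_index=4, training_gain=2.0)
        rates = mix_signals(generate_signals(c, 5.0, 0), c)
        boosted = apply_training_boost(rates, c)
        np.testing.assert_allclose(boosted[3], 2.0 * rates[3])  # input 4
        assert boosted[8] is not rates[8] or True
        np.testing.assert_array_equal(boosted[8], rates[8])  # input 9 untouched
        np.testing.assert_allclose(boosted[2], 1.5 * rates[2])  # neighbor gain

    def test_boundary_clip_no_wraparound(self):
        c = cfg(training_index=1, training_gain=2.0)
        g = training_gain_vector(c)
        assert g[0] == 2.0 and g[1] == 1.5
        assert np.all(g[2:] == 1.0)  # no contribution wraps to the last index

    def test_neutral_profile_under_unit_gain(self):
        c = cfg(training_index=5, training_gain=1.0)
        np.testing.assert_array_equal(training_gain_vector(c), np.ones(10))


class TestPoissonSampling:
    def test_zero_rate_gives_empty_trains(self):
        trains = sample_poisson_spikes(np.zeros((3, 1000)), 1e-4, 0)
        assert all(len(s) == 0 for s in trains.spikes)

    def test_rate_dt_overflow_rejected(self):
        with pytest.raises(ConfigurationError, match="decrease dt"):
            sample_poisson_spikes(np.full((1, 10), 20000.0), 1e-4, 0)

    def test_spike_times_strictly_increasing_within_bins(self):
        c = cfg(n_inputs=3, base_rate=50.0)
        trains = generate_ensemble(c, 5.0, 9)
        for s, b in zip(trains.spikes, trains.bins):
            assert np.all(np.diff(s) > 0)
            assert len(np.unique(b)) == len(b)  # at most one spike per bin
            assert np.all((s >= 0) & (s < trains.duration))

    def test_poisson_count_statistics(self):
        # 10 Hz for 100 s -> 1000 expected; mean over 50 trials within 3 SE
        rates = np.full((1, 100_000), 10.0)
        counts = [
            len(sample_poisson_spikes(rates, 1e-3, seed).spikes[0])
            for seed in range(50)
        ]
        se = np.sqrt(1000.0 / 50)
        assert abs(np.mean(counts) - 1000.0) < 3 * se

    def test_halving_dt_preserves_mean_count(self):
        coarse = [
            len(sample_poisson_spikes(np.full((1, 20_000), 20.0), 1e-3, s).spikes[0])
            for s in range(30)
        ]
        fine = [
            len(
                sample_poisson_spikes(
                    np.full((1, 20_000), 20.0), 5e-4, s, signal_dt=1e-3
                ).spikes[0]
            )
            for s in range(30)
        ]
        se = np.sqrt(400.0 / 30) * np.sqrt(2)
        assert abs(np.mean(coarse) - np.mean(fine)) < 3 * se


class TestEnsemble:
    def test_rate_conservation_untrained(self):
        c = cfg(n_inputs=6)
        trains = generate_ensemble(c, 200.0, 4)
        rates = trains.counts() / trains.duration
        assert np.allclose(rates, 10.0, atol=1.5)

    def test_boost_locality_bit_identical(self):
        c_off = cfg(n_inputs=10)
        c_on = cfg(n_inputs=10, training_index=4, training_gain=2.0)
        a = generate_ensemble(c_off, 10.0, 77)
        b = generate_ensemble(c_on, 10.0, 77)
        for i in (0, 6, 7, 8, 9):  # outside boosted neighborhood {3,4,5} (1-based 3..5)
            np.testing.assert_array_equal(a.spikes[i], b.spikes[i])
        # training input itself has more spikes
        assert len(b.spikes[3]) > len(a.spikes[3])

    def test_merged_events_sorted_and_complete(self, small_ensemble):
        _, trains = small_ensemble
        bins, ids = trains.merged_events()
        assert np.all(np.diff(bins) >= 0)
        assert len(bins) == trains.counts().sum()
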