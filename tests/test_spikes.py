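"""Noise estimation, threshold detection, cutouts, and PCA sorting."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import linear_sum_assignment

import meakit as mk
from meakit.errors import InputError
from meakit.spikes import _crossing_events, _enforce_dead_time
from meakit.synthetic import spike_template

from conftest import oracle_detect

RATE = 30000.0


def best_match_agreement(labels, truth):
    """Label agreement after optimal unit <-> class matching."""
    k = max(labels.max(), truth.max()) + 1
    cost = np.zeros((k, k))
    for a, b in zip(labels, truth):
        cost[a, b] -= 1
    rows, cols = linear_sum_assignment(cost)
    mapping = dict(zip(rows, cols))
    return np.mean([mapping[a] == b for a, b in zip(labels, truth)])


class TestEstimateNoise:
    def test_unit_gaussian_recovers_sigma_one(self):
        x = np.random.default_rng(0).standard_normal(1_000_000)
        assert mk.estimate_noise(x) == pytest.approx(1.0, rel=0.01)

    def test_scaled_gaussian_recovers_sigma(self):
        x = 3.0 * np.random.default_rng(1).standard_normal(1_000_000)
        assert mk.estimate_noise(x) == pytest.approx(3.0, rel=0.01)

    def test_all_zero_trace(self):
        assert mk.estimate_noise(np.zeros(100)) == 0.0

    def test_empty_trace_rejected(self):
        with pytest.raises(InputError):
            mk.estimate_noise(np.empty(0))

    @given(c=st.floats(-10, 10).filter(lambda v: abs(v) > 1e-6), seed=st.integers(0, 1000))
    def test_scale_equivariance(self, c, seed):
        x = np.random.default_rng(seed).standard_normal(1000)
        assert mk.estimate_noise(c * x) == pytest.approx(abs(c) * mk.estimate_noise(x))


class TestDetect:
    def _noise_with_events(self, rng, peaks, times_s, duration=1.0):
        n = int(duration * RATE)
        trace = rng.standard_normal(n)
        template, trough = spike_template(1.0, 0.3, RATE)
        for peak, t in zip(peaks, times_s):
            i = int(t * RATE) - trough
            trace[i : i + template.size] += peak * template
        return trace

    def test_three_injected_events_found_at_injection_times(self, rng):
        times = [0.2, 0.5, 0.8]
        trace = self._noise_with_events(rng, [10, 10, 10], times)
        rec = mk.Recording(trace[None, :], rate=RATE)
        trains, cutouts = mk.detect_spikes(rec)
        assert len(trains.trains[0]) == 3
        np.testing.assert_allclose(trains.trains[0], times, atol=1.5 / RATE)
        assert cutouts.n_events == 3

    def test_all_zero_recording_yields_empty_trains(self):
        rec = mk.Recording(np.zeros((2, 3000)), rate=RATE)
        with pytest.warns(UserWarning, match="flat"):
            trains, cutouts = mk.detect_spikes(rec)
        assert trains.n_spikes() == 0 and cutouts.n_events == 0

    def test_dead_time_keeps_first_of_close_pair(self, rng):
        cfg = mk.DetectionConfig(dead_time_s=0.002)
        t2 = 0.5 + 0.5 * cfg.dead_time_s
        trace = self._noise_with_events(rng, [10, 10], [0.5, t2])
        trains, _ = mk.detect_spikes(mk.Recording(trace[None, :], rate=RATE), cfg)
        assert len(trains.trains[0]) == 1
        assert trains.trains[0][0] == pytest.approx(0.5, abs=1.5 / RATE)

    def test_matches_bruteforce_oracle_on_random_traces(self):
        cfg = mk.DetectionConfig()
        dead = int(round(cfg.dead_time_s * RATE))
        pre = int(round(cfg.pre_s * RATE))
        post = int(round(cfg.post_s * RATE))
        rng = np.random.default_rng(99)
        for _ in range(20):
            trace = rng.standard_normal(rng.integers(1000, 10_000)) * rng.uniform(0.5, 3)
            sigma = mk.estimate_noise(trace)
            expected = oracle_detect(trace, 5 * sigma, dead, pre, post)
            trains, _ = mk.detect_spikes(mk.Recording(trace[None, :], rate=RATE), cfg)
            got = np.round(trains.trains[0] * RATE).astype(int).tolist()
            assert got == expected

    def test_false_event_rate_on_pure_noise_is_low(self):
        rng = np.random.default_rng(7)
        rec = mk.Recording(rng.standard_normal((4, int(10 * RATE))), rate=RATE)
        trains, _ = mk.detect_spikes(rec)
        rate_per_channel = trains.n_spikes() / 4 / 10.0
        assert rate_per_channel < 0.2


class TestCutouts:
    def test_window_length_and_alignment(self, rng):
        trace = 0.1 * rng.standard_normal(int(RATE * 2))
        template, trough = spike_template(12.0, 0.3, RATE)
        i = int(1.0 * RATE) - trough
        trace[i : i + template.size] += template
        rec = mk.Recording(trace[None, :], rate=RATE)
        trains = mk.SpikeTrainSet(trains={0: np.array([1.0])}, duration=2.0)
        cuts = mk.extract_cutouts(rec, trains, pre_s=0.001, post_s=0.001)
        assert cuts.snippets.shape == (1, 61)  # 30 + 30 + 1 samples at 30 kHz
        assert np.argmin(cuts.snippets[0]) == cuts.pre_samples

    def test_boundary_event_dropped_and_reported(self, rng):
        rec = mk.Recording(rng.standard_normal((1, int(RATE))), rate=RATE)
        trains = mk.SpikeTrainSet(trains={0: np.array([0.0002, 0.5])}, duration=1.0)
        cuts = mk.extract_cutouts(rec, trains, pre_s=0.001, post_s=0.001)
        assert cuts.n_events == 1
        assert cuts.dropped == 1


class TestSort:
    def _two_unit_cutouts(self, rng, n=200):
        t1, _ = spike_template(8.0, 0.2, RATE)
        t2, _ = spike_template(4.0, 0.5, RATE)
        width = max(t1.size, t2.size)
        t1 = np.pad(t1, (0, width - t1.size))
        t2 = np.pad(t2, (0, width - t2.size))
        truth = rng.integers(0, 2, size=n)
        X = np.where(truth[:, None] == 0, t1, t2) + 0.3 * rng.standard_normal((n, width))
        pre = width // 2
        return mk.CutoutSet(
            snippets=X, pre_samples=pre, post_samples=width - pre - 1, rate=RATE
        ), truth

    def test_two_templates_recovered_with_high_agreement(self, rng):
        cuts, truth = self._two_unit_cutouts(rng)
        result = mk.sort_spikes(cuts, n_components=2, seed=0)
        assert result.n_units == 2
        assert best_match_agreement(result.labels, truth) >= 0.95

    def test_identical_cutouts_give_single_unit(self):
        X = np.tile(np.linspace(-5, 5, 31), (20, 1))
        cuts = mk.CutoutSet(snippets=X, pre_samples=15, post_samples=15, rate=RATE)
        with pytest.warns(UserWarning, match="zero-variance"):
            result = mk.sort_spikes(cuts)
        assert result.n_units == 1

    def test_permuting_events_permutes_labels_consistently(self, rng):
        cuts, _ = self._two_unit_cutouts(rng, n=100)
        perm = rng.permutation(100)
        shuffled = mk.CutoutSet(
            snippets=cuts.snippets[perm],
            pre_samples=cuts.pre_samples,
            post_samples=cuts.post_samples,
            rate=RATE,
        )
        a = mk.sort_spikes(cuts, seed=0).labels
        b = mk.sort_spikes(shuffled, seed=0).labels
        assert best_match_agreement(b, a[perm]) == 1.0

    def test_too_few_events_rejected(self, rng):
        cuts = mk.CutoutSet(
            snippets=rng.standard_normal((3, 31)), pre_samples=15, post_samples=15, rate=RATE
        )
        with pytest.raises(InputError):
            mk.sort_spikes(cuts, n_components=2)


class TestInternals:
    @given(seed=st.integers(0, 500), thr=st.floats(0.5, 3.0))
    def test_crossing_events_match_oracle(self, seed, thr):
        trace = np.random.default_rng(seed).standard_normal(500)
        got = _enforce_dead_time(_crossing_events(trace, thr, "negative"), 10)
        expected = oracle_detect(trace, thr, 10, 0, 0)
        assert got.tolist() == [i for i in expected]
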