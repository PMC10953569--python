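"""Channel and network statistics against independent oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import meakit as mk
from meakit.errors import InputError

from conftest import oracle_bursts, oracle_correlation, oracle_quantile


class TestFiringRates:
    def test_count_over_duration(self):
        trains = mk.SpikeTrainSet(
            trains={0: np.linspace(0.5, 119.5, 120), 1: np.empty(0)}, duration=120.0
        )
        rates = mk.firing_rates(trains)
        assert rates[0] == pytest.approx(1.0)
        assert rates[1] == 0.0

    def test_poisson_rate_within_three_se(self, rng):
        lam, T = 2.0, 100.0
        ts = np.sort(rng.uniform(0, T, rng.poisson(lam * T)))
        trains = mk.SpikeTrainSet(trains={0: np.unique(ts)}, duration=T)
        se = np.sqrt(lam / T)
        assert abs(mk.firing_rates(trains)[0] - lam) < 3 * se


class TestActiveChannels:
    def test_strict_exceed_rule(self):
        mask = mk.active_channels({0: 0.6, 1: 0.5, 2: 0.0})
        assert mask == {0: True, 1: False, 2: False}


class TestSnr:
    def _make(self, trace, peaks, rate=30000.0):
        rec = mk.Recording(trace[None, :], rate=rate)
        n = len(peaks)
        snips = np.zeros((n, 3))
        snips[:, 1] = peaks
        cuts = mk.CutoutSet(
            snippets=snips, pre_samples=1, post_samples=1,
            channels=np.zeros(n, dtype=int), timestamps=np.arange(n, dtype=float),
            rate=rate,
        )
        return rec, cuts

    def test_definition_mean_peak_over_trace_std(self, rng):
        trace = 10.0 * rng.standard_normal(100000)
        trace *= 10.0 / np.std(trace)  # pin std exactly to 10 µV
        rec, cuts = self._make(trace, [-40.0, -50.0, -60.0])
        assert mk.snr(rec, cuts)[0] == pytest.approx(5.0)

    def test_scale_invariance(self, rng):
        trace = rng.standard_normal(5000)
        rec1, cuts1 = self._make(trace, [-8.0, -6.0])
        rec2, cuts2 = self._make(3.0 * trace, [-24.0, -18.0])
        assert mk.snr(rec2, cuts2)[0] == pytest.approx(mk.snr(rec1, cuts1)[0])

    def test_no_events_reported_missing(self, rng):
        rec = mk.Recording(rng.standard_normal((1, 1000)), rate=30000.0)
        cuts = mk.CutoutSet(snippets=np.empty((0, 3)), pre_samples=1, post_samples=1)
        assert np.isnan(mk.snr(rec, cuts)[0])

    def test_constructed_channel_hits_target_snr(self):
        # sparse spikes of peak 60 µV on noise of sigma 10 µV: SNR ~ 6
        cfg = mk.SimConfig(
            seed=5, layout=mk.make_rect(59), duration_s=5.0,
            template_peak_uv=60.0, noise_sigma_uv=10.0,
            baseline_rate_hz=1.0, burst_rate_hz=0.0,
        )
        trains = mk.simulate_trains(cfg)
        rec = mk.render_recording(trains, cfg)
        cuts = mk.extract_cutouts(rec, trains)  # ground-truth alignment
        snrs = [v for v in mk.snr(rec, cuts).values() if np.isfinite(v)]
        assert np.median(snrs) == pytest.approx(6.0, rel=0.10)


class TestBinning:
    def test_halfopen_bin_convention(self):
        trains = mk.SpikeTrainSet(trains={0: np.array([0.005, 0.015])}, duration=0.02)
        counts, _ = mk.bin_spiketrains(trains, 0.010)
        assert counts.tolist() == [[1, 1]]

    def test_spike_at_bin_edge_goes_right(self):
        trains = mk.SpikeTrainSet(trains={0: np.array([0.010])}, duration=0.03)
        counts, _ = mk.bin_spiketrains(trains, 0.010)
        assert counts.tolist() == [[0, 1, 0]]

    @given(seed=st.integers(0, 2000))
    def test_total_count_conserved(self, seed):
        rng = np.random.default_rng(seed)
        ts = np.unique(rng.uniform(0, 10, rng.integers(0, 100)))
        trains = mk.SpikeTrainSet(trains={0: ts}, duration=10.0)
        counts, _ = mk.bin_spiketrains(trains, 0.010)
        assert counts.sum() == len(ts)


class TestCorrelation:
    def test_identical_trains_fully_correlated(self):
        ts = np.linspace(0.05, 1.95, 23)
        trains = mk.SpikeTrainSet(trains={0: ts, 1: ts.copy()}, duration=2.0)
        counts, chans = mk.bin_spiketrains(trains)
        corr = mk.correlation_matrix(counts, channel_ids=chans)
        assert corr.values[0, 1] == pytest.approx(1.0)
        np.testing.assert_allclose(np.diag(corr.values), 1.0)
        np.testing.assert_allclose(corr.values, corr.values.T)

    def test_independent_poisson_trains_uncorrelated(self, rng):
        lam, T = 5.0, 200.0
        trains = {
            ch: np.unique(np.sort(rng.uniform(0, T, rng.poisson(lam * T))))
            for ch in range(6)
        }
        counts, chans = mk.bin_spiketrains(mk.SpikeTrainSet(trains=trains, duration=T))
        corr = mk.correlation_matrix(counts, channel_ids=chans)
        off = corr.values[~np.eye(6, dtype=bool)]
        assert np.mean(np.abs(off) < 0.05) >= 0.95

    def test_matches_two_pass_oracle(self, rng):
        for _ in range(5):
            X = rng.poisson(2.0, size=(5, 50)).astype(float)
            corr = mk.correlation_matrix(X)
            expected = oracle_correlation(X)
            np.testing.assert_allclose(corr.values, expected, atol=1e-12)

    def test_zero_variance_channel_is_nan_not_zero(self):
        X = np.array([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]])
        corr = mk.correlation_matrix(X)
        assert np.isnan(corr.values[0, 1]) and np.isnan(corr.values[1, 1])

    def test_single_bin_rejected(self):
        with pytest.raises(InputError):
            mk.correlation_matrix(np.ones((2, 1)))


class TestBursts:
    def test_regular_slow_train_has_no_bursts(self):
        assert mk.detect_bursts(np.arange(0, 10, 1.0), 0.1, 3) == []

    def test_embedded_fast_run_is_one_burst(self):
        ts = np.sort(np.concatenate([[0.1, 2.9], 1.0 + np.arange(10) * 0.01]))
        bursts = mk.detect_bursts(ts, max_isi_s=0.02, min_spikes=5)
        assert len(bursts) == 1
        assert bursts[0][2] == 10

    def test_two_separated_bursts(self):
        ts = np.sort(np.concatenate([np.arange(5) * 0.01, 2.0 + np.arange(5) * 0.01]))
        bursts = mk.detect_bursts(ts, 0.02, 3)
        assert len(bursts) == 2

    @given(seed=st.integers(0, 5000))
    def test_matches_runscan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ts = np.unique(np.cumsum(rng.exponential(0.05, size=rng.integers(2, 60))))
        got = mk.detect_bursts(ts, 0.06, 3)
        assert got == oracle_bursts(ts.tolist(), 0.06, 3)


class TestBoxSummary:
    def test_interpolated_quartiles_on_one_to_eight(self):
        s = mk.box_summary(np.arange(1, 9, dtype=float))
        assert s.median == pytest.approx(oracle_quantile(range(1, 9), 0.5)) == 4.5
        assert s.q1 == pytest.approx(oracle_quantile(range(1, 9), 0.25)) == 2.75
        assert s.q3 == pytest.approx(oracle_quantile(range(1, 9), 0.75)) == 6.25

    def test_constant_data_no_outliers(self):
        s = mk.box_summary(np.full(10, 3.3))
        assert s.iqr == 0.0 and len(s.outliers) == 0
        assert s.whisker_low == s.whisker_high == 3.3

    def test_extreme_value_flagged_as_outlier(self):
        values = np.concatenate([np.arange(1, 9, dtype=float), [100.0]])
        s = mk.box_summary(values)
        assert 100.0 in s.outliers
        assert s.whisker_high < 100.0

    def test_whiskers_within_data_range(self, rng):
        v = rng.normal(size=200)
        s = mk.box_summary(v)
        assert v.min() <= s.whisker_low <= s.q1
        assert s.q3 <= s.whisker_high <= v.max()

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            mk.box_summary([])


class TestFiringMap:
    def test_identity_join(self):
        lay = mk.make_rect(59)
        rates = {int(c): float(c) for c in lay.channel_map}
        fmap = mk.firing_map(rates, lay)
        assert len(fmap) == 59
        np.testing.assert_allclose(fmap["value"], fmap["channel"])

    def test_missing_channel_is_join_error(self):
        lay = mk.make_rect(59)
        with pytest.raises(InputError, match="missing"):
            mk.firing_map({0: 1.0}, lay)

    def test_wellwise_means_via_groupby(self):
        lay = mk.make_multiwell(4, 32)
        rates = {int(c): float(lay.well_id[i]) for i, c in enumerate(lay.channel_map)}
        fmap = mk.firing_map(rates, lay)
        means = fmap.groupby("well_id")["value"].mean()
        np.testing.assert_allclose(means.to_numpy(), [0, 1, 2, 3])
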