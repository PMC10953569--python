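"""Ground-truth simulator: statistical targets, determinism, full-chain recovery."""

import numpy as np
import pytest

import meakit as mk
from meakit.synthetic import spike_template


class TestSimulateTrains:
    def test_poisson_background_count_within_ci(self):
        cfg = mk.SimConfig(
            seed=4, layout=mk.make_rect(59), duration_s=100.0,
            baseline_rate_hz=2.0, burst_rate_hz=0.0,
        )
        trains = mk.simulate_trains(cfg)
        counts = np.array([len(ts) for ts in trains.trains.values()])
        # each channel: Poisson(200), 3 s.e. band
        assert np.all(np.abs(counts - 200) < 3 * np.sqrt(200) + 3)

    def test_silent_config_gives_empty_trains(self):
        cfg = mk.SimConfig(seed=0, duration_s=10.0, baseline_rate_hz=0.0, burst_rate_hz=0.0)
        assert mk.simulate_trains(cfg).n_spikes() == 0

    def test_same_seed_reproducible(self):
        cfg = mk.SimConfig(seed=9, duration_s=20.0)
        a, b = mk.simulate_trains(cfg), mk.simulate_trains(mk.SimConfig(seed=9, duration_s=20.0))
        assert a == b

    def test_well_sync_shares_bursts_within_wells_only(self):
        lay = mk.make_multiwell(4, 16)
        cfg = mk.SimConfig(
            seed=2, layout=lay, duration_s=60.0, baseline_rate_hz=0.0,
            burst_rate_hz=0.2, well_sync=True, intra_burst_isi_s=0.01,
        )
        trains = mk.simulate_trains(cfg)
        # first spike of each channel marks its well's first burst onset
        first = {int(ch): trains.trains[int(ch)][0] for ch in lay.channel_map
                 if len(trains.trains[int(ch)])}
        by_well = {}
        for i, ch in enumerate(lay.channel_map):
            if int(ch) in first:
                by_well.setdefault(lay.well_id[i], []).append(first[int(ch)])
        onsets = [min(v) for v in by_well.values()]
        for v in by_well.values():
            assert np.ptp(np.array(v)) < 0.05  # shared within well
        assert np.ptp(np.array(onsets)) > 0.05  # independent across wells

    def test_refractory_interval_enforced(self):
        cfg = mk.SimConfig(seed=3, duration_s=30.0, baseline_rate_hz=20.0)
        trains = mk.simulate_trains(cfg)
        for ts in trains.trains.values():
            if len(ts) > 1:
                assert np.diff(ts).min() >= cfg.refractory_s - 1e-12


class TestRenderRecording:
    def test_single_spike_zero_noise_reproduces_template(self):
        lay = mk.make_rect(59)
        cfg = mk.SimConfig(seed=0, layout=lay, duration_s=1.0, noise_sigma_uv=0.0,
                           attenuation_um=1e-9)
        trains = mk.SpikeTrainSet(
            trains={int(ch): np.array([0.5]) if i == 0 else np.empty(0)
                    for i, ch in enumerate(lay.channel_map)},
            duration=1.0,
        )
        rec = mk.render_recording(trains, cfg)
        template, trough = spike_template(cfg.template_peak_uv, cfg.template_width_ms, cfg.rate_hz)
        centre = int(0.5 * cfg.rate_hz)
        seg = rec.signal[0, centre - trough : centre - trough + template.size]
        np.testing.assert_allclose(seg, template, atol=1e-12)
        assert rec.signal[0].min() == pytest.approx(-cfg.template_peak_uv)

    def test_zero_noise_detection_is_perfect(self):
        cfg = mk.SimConfig(seed=6, layout=mk.make_rect(59), duration_s=5.0,
                           noise_sigma_uv=0.0, baseline_rate_hz=1.0, burst_rate_hz=0.1)
        trains = mk.simulate_trains(cfg)
        rec = mk.render_recording(trains, cfg)
        rec.signal += 0.5 * np.random.default_rng(0).standard_normal(rec.signal.shape)
        filt = mk.apply_filter(rec)
        detected, _ = mk.detect_spikes(filt)
        for ch, ts in trains.trains.items():
            got = detected.trains[ch]
            # 100% recall: every true spike matched within 1 ms
            for t in ts:
                assert np.min(np.abs(got - t)) < 0.001 if len(got) else len(ts) == 0

    def test_doubling_noise_doubles_estimate(self):
        lay = mk.make_rect(59)
        base = dict(layout=lay, duration_s=2.0, baseline_rate_hz=0.5, burst_rate_hz=0.0)
        r1 = mk.render_recording(
            mk.simulate_trains(mk.SimConfig(seed=8, noise_sigma_uv=5.0, **base)),
            mk.SimConfig(seed=8, noise_sigma_uv=5.0, **base),
        )
        r2 = mk.render_recording(
            mk.simulate_trains(mk.SimConfig(seed=8, noise_sigma_uv=10.0, **base)),
            mk.SimConfig(seed=8, noise_sigma_uv=10.0, **base),
        )
        n1 = mk.estimate_noise(r1.signal[0])
        n2 = mk.estimate_noise(r2.signal[0])
        assert n2 / n1 == pytest.approx(2.0, rel=0.02)

    def test_snr_monotone_in_template_peak(self):
        lay = mk.make_rect(59)
        medians = []
        for peak in (30.0, 60.0, 120.0):
            cfg = mk.SimConfig(seed=13, layout=lay, duration_s=3.0,
                               template_peak_uv=peak, noise_sigma_uv=6.0,
                               baseline_rate_hz=2.0, burst_rate_hz=0.0)
            trains = mk.simulate_trains(cfg)
            filt = mk.apply_filter(mk.render_recording(trains, cfg))
            _, cuts = mk.detect_spikes(filt)
            vals = [v for v in mk.snr(filt, cuts).values() if np.isfinite(v)]
            medians.append(np.median(vals))
        assert medians[0] < medians[1] < medians[2]


class TestRenderFluorescence:
    def test_bursts_recovered_through_calcium_chain(self):
        cfg = mk.SimConfig(
            seed=1, layout=mk.make_rect(59), duration_s=40.0,
            baseline_rate_hz=0.2, burst_rate_hz=0.0,
            evoked_times=[5.0, 12.0, 19.0, 26.0, 33.0],
        )
        trains = mk.simulate_trains(cfg)
        fluor = mk.render_fluorescence(trains, cfg)
        dff = mk.compute_dff(fluor)
        onsets = mk.detect_calcium_events(dff, threshold=0.2, min_separation_s=4.0,
                                          frame_rate_hz=cfg.frame_rate_hz)
        assert len(onsets) == 5

    def test_empty_trains_flat_at_f0(self):
        cfg = mk.SimConfig(seed=0, duration_s=5.0, calcium_noise=0.0)
        trains = mk.SpikeTrainSet(trains={0: np.empty(0)}, duration=5.0)
        fluor = mk.render_fluorescence(trains, cfg)
        np.testing.assert_allclose(fluor.intensities, cfg.f0)

    def test_seed_reproducibility(self):
        cfg = mk.SimConfig(seed=5, duration_s=10.0)
        trains = mk.simulate_trains(cfg)
        a = mk.render_fluorescence(trains, cfg)
        b = mk.render_fluorescence(trains, cfg)
        np.testing.assert_array_equal(a.intensities, b.intensities)
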