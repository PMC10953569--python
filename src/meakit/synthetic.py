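"""Ground-truth simulator for the whole analysis chain.

Generates, from one seeded configuration: per-channel spike trains with
population bursts (Poisson background + synchronized burst events, optionally
shared only within wells), layout-aware extracellular voltage traces (a
stereotyped biphasic template per unit, exponentially attenuated on
neighbouring electrodes, plus Gaussian noise), and a matched fluorescence
trace (population rate convolved with a fast-rise / slow-decay calcium
kernel).  Every downstream operation — filtering, detection, sorting,
metrics, dF/F0 — can thus be checked against known ground truth.

The defaults emulate a healthy 2D culture on a 30 kHz MEA: ~2 Hz background
firing, population bursts every ~5 s of ~10 spikes per channel at ~100 Hz
intra-burst rate, spike peaks of 60 µV over 6 µV noise, calcium transients
with <150 ms rise and ~3 s decay sampled at 100 fps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .io import Recording, SpikeTrainSet
from .calcium import FluorescenceTrace
from .layouts import ElectrodeLayout, make_rect

__all__ = ["SimConfig", "simulate_trains", "render_recording", "render_fluorescence"]


@dataclass
class SimConfig:
    """Simulation parameters (units in field names; see module docstring)."""

    seed: int = 0
    layout: ElectrodeLayout | None = None
    duration_s: float = 60.0
    rate_hz: float = 30000.0
    baseline_rate_hz: float = 2.0
    burst_rate_hz: float = 0.2
    burst_size: int = 10
    intra_burst_isi_s: float = 0.01
    template_peak_uv: float = 60.0
    template_width_ms: float = 0.3
    noise_sigma_uv: float = 6.0
    attenuation_um: float = 60.0
    rise_s: float = 0.1
    decay_s: float = 3.0
    frame_rate_hz: float = 100.0
    f0: float = 100.0
    calcium_gain: float = 0.05
    calcium_noise: float = 0.002
    well_sync: bool = False
    refractory_s: float = 0.002
    evoked_times: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.layout is None:
            self.layout = make_rect(59)
        if min(self.baseline_rate_hz, self.burst_rate_hz, self.noise_sigma_uv) < 0:
            raise ParameterError("rates and noise sigma must be >= 0")
        if self.rise_s >= self.decay_s:
            raise ParameterError("calcium kernel needs rise_s < decay_s")
        if self.duration_s <= 0 or self.rate_hz <= 0:
            raise ParameterError("duration and sampling rate must be positive")


def _thin_refractory(ts: np.ndarray, refractory: float) -> np.ndarray:
    if ts.size == 0:
        return ts
    kept = [ts[0]]
    for t in ts[1:]:
        if t - kept[-1] >= refractory:
            kept.append(t)
    return np.asarray(kept)


def simulate_trains(config: SimConfig) -> SpikeTrainSet:
    """Draw ground-truth spike trains.

    Per channel: homogeneous Poisson background at ``baseline_rate_hz``
    superposed with population bursts.  Burst event times are Poisson at
    ``burst_rate_hz``; with ``well_sync`` they are drawn independently per
    well (shared by that well's channels only), otherwise shared network-wide.
    Within a burst each channel fires ``burst_size`` spikes at the
    intra-burst interval with small per-channel jitter.  Trains are thinned
    to the refractory interval.  Identical seeds give identical output.
    """
    rng = np.random.default_rng(config.seed)
    layout = config.layout
    duration = config.duration_s
    channels = list(layout.channel_map)

    # burst skeleton(s)
    def draw_burst_times(r: np.random.Generator) -> np.ndarray:
        n = r.poisson(config.burst_rate_hz * duration)
        times = np.sort(r.uniform(0, duration, size=n))
        if config.evoked_times:
            times = np.sort(np.concatenate([times, np.asarray(config.evoked_times)]))
        return times

    if config.well_sync:
        burst_times_by_well = {w: draw_burst_times(rng) for w in layout.wells()}
    else:
        shared = draw_burst_times(rng)
        burst_times_by_well = {w: shared for w in layout.wells()}

    trains: dict = {}
    for elec_idx, ch in enumerate(channels):
        well = layout.well_id[elec_idx]
        n_bg = rng.poisson(config.baseline_rate_hz * duration)
        ts = rng.uniform(0, duration, size=n_bg)
        for bt in burst_times_by_well[well]:
            isis = config.intra_burst_isi_s * (1 + 0.2 * rng.standard_normal(config.burst_size))
            isis = np.clip(isis, config.intra_burst_isi_s * 0.2, None)
            spikes = bt + np.concatenate([[0.0], np.cumsum(isis[:-1])])
            ts = np.concatenate([ts, spikes])
        ts = np.sort(ts)
        ts = ts[(ts >= 0) & (ts < duration)]
        ts = _thin_refractory(ts, config.refractory_s)
        trains[int(ch)] = ts
    return SpikeTrainSet(trains=trains, duration=duration, channel_ids=np.asarray(channels))


def spike_template(
    peak_uv: float, width_ms: float, rate_hz: float
) -> tuple[np.ndarray, int]:
    """Stereotyped biphasic extracellular waveform (negative main phase).

    Difference-of-Gaussians: a sharp negative trough of the requested peak
    amplitude followed by a broader positive rebound.  Returns the sampled
    template and the index of its trough (the alignment point).
    """
    s1 = width_ms * 1e-3 / 2.0  # trough sd (s)
    half = 2e-3  # 2 ms on each side
    t = np.arange(-half, half + 0.5 / rate_hz, 1.0 / rate_hz)
    raw = -np.exp(-(t**2) / (2 * s1**2)) + 0.45 * np.exp(
        -((t - 2.2 * s1) ** 2) / (2 * (2.0 * s1) ** 2)
    )
    template = peak_uv * raw / np.abs(raw.min())
    return template, int(np.argmin(template))


def render_recording(trains: SpikeTrainSet, config: SimConfig) -> Recording:
    """Render spike trains to an extracellular voltage block.

    Each spike inserts its unit's template on the unit's home electrode; on
    other electrodes the amplitude is scaled by ``exp(-d / attenuation_um)``
    (contributions below 0.1% are skipped).  Independent Gaussian noise of
    ``noise_sigma_uv`` is added to every channel; superposition is linear.
    """
    layout = config.layout
    rate = config.rate_hz
    n_samples = int(round(trains.duration * rate))
    channels = list(layout.channel_map)
    n_ch = len(channels)
    rng = np.random.default_rng(config.seed + 1)

    signal = (
        config.noise_sigma_uv * rng.standard_normal((n_ch, n_samples))
        if config.noise_sigma_uv > 0
        else np.zeros((n_ch, n_samples))
    )
    template, trough = spike_template(config.template_peak_uv, config.template_width_ms, rate)
    tlen = template.size

    # pairwise attenuation, sparsified
    pos = layout.positions
    for src_idx, ch in enumerate(channels):
        ts = trains.trains.get(int(ch), np.empty(0))
        if ts.size == 0:
            continue
        d = np.hypot(*(pos - pos[src_idx]).T)
        gains = np.exp(-d / config.attenuation_um)
        targets = np.flatnonzero(gains > 1e-3)
        for t in ts:
            centre = int(round(t * rate))
            a = centre - trough
            b = a + tlen
            ta, tb = max(a, 0), min(b, n_samples)
            if ta >= tb:
                continue
            seg = template[ta - a : tb - a]
            for tgt in targets:
                signal[tgt, ta:tb] += gains[tgt] * seg
    return Recording(signal=signal, rate=rate, channel_ids=np.asarray(channels))


def calcium_kernel(rise_s: float, decay_s: float, frame_rate_hz: float) -> np.ndarray:
    """Fast-rise / slow-decay transient kernel sampled at the frame rate."""
    t = np.arange(0, decay_s * 5, 1.0 / frame_rate_hz)
    k = (1.0 - np.exp(-t / rise_s)) * np.exp(-t / decay_s)
    return k


def render_fluorescence(trains: SpikeTrainSet, config: SimConfig) -> FluorescenceTrace:
    """Render spike trains to a matched ROI-mean fluorescence trace.

    The per-frame population rate (spikes per channel) is convolved with the
    calcium kernel, scaled by ``calcium_gain`` (dF/F0 per spike per channel),
    offset by ``f0`` and given multiplicative Gaussian noise — i.e.
    ``F = F0 * (1 + gain * (rate (*) kernel)) + noise``.
    """
    fr = config.frame_rate_hz
    n_frames = int(round(trains.duration * fr))
    counts = np.zeros(n_frames)
    n_ch = max(len(trains.trains), 1)
    for ts in trains.trains.values():
        if ts.size:
            idx = np.clip(np.floor(ts * fr).astype(int), 0, n_frames - 1)
            np.add.at(counts, idx, 1.0)
    counts /= n_ch
    kernel = calcium_kernel(config.rise_s, config.decay_s, fr)
    drive = np.convolve(counts, kernel)[:n_frames]
    rng = np.random.default_rng(config.seed + 2)
    noise = config.calcium_noise * config.f0 * rng.standard_normal(n_frames)
    intensities = config.f0 * (1.0 + config.calcium_gain * drive) + noise
    return FluorescenceTrace(intensities=intensities, frame_rate_hz=fr)
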