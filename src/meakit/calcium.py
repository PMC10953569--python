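"""Calcium fluorescence analysis and alignment with electrophysiology.

A calcium indicator reports population activity as slow fluorescence
transients; activity is quantified as the normalized change
``dF/F0 = (F - F0) / F0`` where ``F`` is the instantaneous and ``F0`` the
initial (baseline) ROI-mean intensity.  Typical acquisition is 100 frames/s.
The electrical counterpart of a culture-wide burst is a local field
potential (LFP) event, obtained by low-pass filtering the extracellular
trace; the two modalities are aligned on their first rising edge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import AlignmentError, InputError, ParameterError
from .io import Recording

__all__ = [
    "FluorescenceTrace",
    "compute_dff",
    "detect_calcium_events",
    "extract_lfp",
    "first_edge_align",
]


@dataclass
class FluorescenceTrace:
    """Frame-timed ROI-mean fluorescence intensity.

    ``intensities`` are arbitrary units; ``frame_rate_hz`` the acquisition
    rate (100 fps typical); ``t0`` the time of the first frame.
    """

    intensities: np.ndarray
    frame_rate_hz: float = 100.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.frame_rate_hz <= 0:
            raise ParameterError("frame rate must be positive")
        if self.intensities.size and not np.all(np.isfinite(self.intensities)):
            raise InputError("fluorescence trace contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.intensities.size

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz


def _baseline(trace: FluorescenceTrace, mode: str) -> float:
    if mode == "initial":
        # mean of the first second of frames pins down "initial intensity"
        n = max(int(round(trace.frame_rate_hz)), 1)
        return float(trace.intensities[:n].mean())
    if mode == "percentile10":
        return float(np.percentile(trace.intensities, 10))
    raise ParameterError(f"unknown baseline mode {mode!r}")


def compute_dff(trace: FluorescenceTrace, baseline_mode: str = "initial") -> np.ndarray:
    """Normalized fluorescence change ``(F - F0)/F0`` per frame.

    ``baseline_mode="initial"`` uses the mean of the first second of frames
    as F0; ``"percentile10"`` uses the 10th percentile (robust to drift).
    The result is dimensionless and invariant to rescaling the raw
    intensities.
    """
    if trace.n_frames == 0:
        raise InputError("empty fluorescence trace")
    f0 = _baseline(trace, baseline_mode)
    if f0 <= 0:
        raise InputError(f"baseline F0 must be positive, got {f0}")
    return (trace.intensities - f0) / f0


def detect_calcium_events(
    dff: np.ndarray,
    threshold: float,
    min_separation_s: float = 1.0,
    frame_rate_hz: float = 100.0,
) -> np.ndarray:
    """Onset times of calcium transients.

    Onsets are upward crossings of ``threshold`` in the dF/F0 series;
    crossings closer than ``min_separation_s`` to the previous accepted onset
    are suppressed (they belong to the same transient).
    """
    if threshold <= 0:
        raise ParameterError("threshold must be positive")
    dff = np.asarray(dff, dtype=np.float64)
    above = dff > threshold
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if above.size and above[0]:
        crossings = np.concatenate([[0], crossings])
    min_gap = min_separation_s * frame_rate_hz
    onsets = []
    for i in crossings:
        if not onsets or i - onsets[-1] >= min_gap:
            onsets.append(int(i))
    return np.asarray(onsets) / frame_rate_hz


def extract_lfp(
    recording: Recording, cutoff_hz: float = 100.0, decimate_to_hz: float | None = 1000.0
) -> Recording:
    """Low-pass filter (and optionally decimate) to the LFP band.

    Fourth-order zero-phase Butterworth low-pass at ``cutoff_hz`` (default
    100 Hz); when ``decimate_to_hz`` is given the result is resampled to
    that rate (must stay >= 2.5x the cutoff to preserve the band).
    """
    if cutoff_hz >= recording.rate / 2:
        raise ParameterError(
            f"cutoff {cutoff_hz} Hz violates Nyquist at rate {recording.rate} Hz"
        )
    sos = sps.butter(4, cutoff_hz, btype="lowpass", fs=recording.rate, output="sos")
    low = sps.sosfiltfilt(sos, recording.signal, axis=-1)
    rate = recording.rate
    if decimate_to_hz is not None:
        if decimate_to_hz < 2.5 * cutoff_hz:
            raise ParameterError(
                f"decimation target {decimate_to_hz} Hz < 2.5x cutoff {cutoff_hz} Hz"
            )
        step = max(int(round(rate / decimate_to_hz)), 1)
        low = low[:, ::step]
        rate = rate / step
    return Recording(
        signal=low,
        rate=rate,
        t0=recording.t0,
        channel_ids=recording.channel_ids.copy(),
        scale=recording.scale,
    )


def _first_edge_time(values: np.ndarray, rate: float, edge_fraction: float) -> float:
    """First upward crossing of edge_fraction * peak, linearly interpolated."""
    v = np.asarray(values, dtype=np.float64)
    peak = v.max()
    if peak <= 0 or not np.isfinite(peak):
        raise AlignmentError("series has no positive peak to define an edge")
    level = edge_fraction * peak
    above = v >= level
    idx = np.flatnonzero(~above[:-1] & above[1:])
    if above[0]:
        return 0.0
    if idx.size == 0:
        raise AlignmentError("series never crosses its edge level")
    i = int(idx[0])
    # linear interpolation between samples i and i+1
    frac = (level - v[i]) / (v[i + 1] - v[i])
    return (i + frac) / rate


def first_edge_align(
    series_a: np.ndarray,
    series_b: np.ndarray,
    rate_a: float,
    rate_b: float | None = None,
    edge_fraction: float = 0.5,
) -> float:
    """Lag between two signals measured on their first rising edges.

    Each series' edge time is the first upward crossing of
    ``edge_fraction x its own peak`` (sub-sample by linear interpolation);
    the returned lag is ``t_edge(a) - t_edge(b)`` in seconds.  A flat series
    raises :class:`AlignmentError`.
    """
    if not 0 < edge_fraction <= 1:
        raise ParameterError("edge_fraction must be in (0, 1]")
    rate_b = rate_b if rate_b is not None else rate_a
    ta = _first_edge_time(series_a, rate_a, edge_fraction)
    tb = _first_edge_time(series_b, rate_b, edge_fraction)
    return ta - tb
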