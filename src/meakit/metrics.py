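"""Channel and network statistics for spike-train data.

Implements the standard single-channel measures (firing rate, the >0.5 Hz
active-channel rule, SNR defined as mean spike peak amplitude over the
standard deviation of the full filtered trace) and network-level measures
(product-moment correlation of 10 ms binned counts, max-ISI burst detection,
box-plot summaries with the 1.5*IQR whisker rule, spatial firing maps).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError, ParameterError
from .io import CutoutSet, Recording, SpikeTrainSet
from .layouts import ElectrodeLayout

__all__ = [
    "BoxSummary",
    "CorrelationMatrix",
    "firing_rates",
    "active_channels",
    "snr",
    "bin_spiketrains",
    "correlation_matrix",
    "detect_bursts",
    "box_summary",
    "firing_map",
]


@dataclass
class BoxSummary:
    """Five-number box-plot summary with the 1.5*IQR whisker rule.

    Whiskers extend from the box by at most 1.5*IQR but are clipped to the
    most extreme data points inside that range; values beyond the whiskers
    are outliers.
    """

    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray
    n: int

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


@dataclass
class CorrelationMatrix:
    """Channel x channel correlation of binned spike counts.

    Entries for zero-variance channels are NaN (undefined, not zero).
    """

    values: np.ndarray
    bin_s: float
    channel_ids: np.ndarray

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    def mean_offdiagonal(self, idx_a=None, idx_b=None) -> float:
        """Mean correlation between two channel groups (off-diagonal only)."""
        v = self.values
        n = v.shape[0]
        if idx_a is None:
            idx_a = np.arange(n)
        if idx_b is None:
            idx_b = np.arange(n)
        vals = []
        for i in idx_a:
            for j in idx_b:
                if i != j and np.isfinite(v[i, j]):
                    vals.append(v[i, j])
        return float(np.mean(vals)) if vals else float("nan")


def firing_rates(spiketrains: SpikeTrainSet) -> dict:
    """Per-channel mean firing rate (Hz): spike count over duration."""
    if spiketrains.duration <= 0:
        raise InputError("duration must be positive")
    return {ch: len(ts) / spiketrains.duration for ch, ts in spiketrains.trains.items()}


def active_channels(rates: dict, threshold_hz: float = 0.5) -> dict:
    """Active-channel mask: a channel is active when its rate *exceeds*
    the threshold (strict inequality; default 0.5 Hz)."""
    return {ch: r > threshold_hz for ch, r in rates.items()}


def snr(filtered: Recording, cutouts: CutoutSet) -> dict:
    """Per-channel signal-to-noise ratio.

    SNR = mean over that channel's events of |peak amplitude| divided by the
    standard deviation of the channel's entire filtered trace.  Channels with
    no events are reported as NaN (undefined), never 0.
    """
    out: dict = {}
    peaks = (
        np.abs(cutouts.snippets[:, cutouts.pre_samples])
        if cutouts.n_events
        else np.empty(0)
    )
    for row, ch in enumerate(filtered.channel_ids):
        sel = cutouts.channels == row
        if cutouts.n_events == 0 or not sel.any():
            out[ch] = float("nan")
            continue
        sd = float(np.std(filtered.signal[row]))
        out[ch] = float(np.mean(peaks[sel]) / sd) if sd > 0 else float("nan")
    return out


def bin_spiketrains(
    spiketrains: SpikeTrainSet, bin_s: float = 0.010
) -> tuple[np.ndarray, np.ndarray]:
    """Bin spike times into counts on half-open bins [k*bin, (k+1)*bin).

    Returns ``(counts, channel_ids)`` with ``counts`` of shape
    ``(n_channels, n_bins)``; row sums equal per-channel spike counts.
    """
    if bin_s <= 0:
        raise ParameterError(f"bin width must be positive, got {bin_s}")
    n_bins = max(int(np.ceil(spiketrains.duration / bin_s)), 1)
    chans = list(spiketrains.trains.keys())
    counts = np.zeros((len(chans), n_bins), dtype=int)
    for i, ch in enumerate(chans):
        ts = spiketrains.trains[ch]
        if ts.size:
            idx = np.floor(ts / bin_s).astype(int)
            idx = np.clip(idx, 0, n_bins - 1)  # spike exactly at duration
            np.add.at(counts[i], idx, 1)
    return counts, np.asarray(chans)


def correlation_matrix(
    binned_counts: np.ndarray, bin_s: float = 0.010, channel_ids=None
) -> CorrelationMatrix:
    """Pairwise product-moment correlation of binned spike counts.

    Zero-variance channels produce NaN rows/columns (reported as missing,
    not imputed).  Requires at least 2 bins.
    """
    X = np.asarray(binned_counts, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] < 2:
        raise InputError("correlation needs a channels x bins matrix with >= 2 bins")
    n = X.shape[0]
    if channel_ids is None:
        channel_ids = np.arange(n)
    sd = X.std(axis=1)
    values = np.full((n, n), np.nan)
    ok = sd > 0
    if ok.any():
        sub = np.corrcoef(X[ok])
        sub = np.atleast_2d(sub)
        ii = np.flatnonzero(ok)
        values[np.ix_(ii, ii)] = np.clip(sub, -1.0, 1.0)
    return CorrelationMatrix(values=values, bin_s=bin_s, channel_ids=np.asarray(channel_ids))


def detect_bursts(
    spiketrain: np.ndarray, max_isi_s: float = 0.1, min_spikes: int = 3
) -> list[tuple[float, float, int]]:
    """Max-ISI burst detection on a single channel.

    A burst is a maximal run of at least ``min_spikes`` consecutive spikes in
    which every inter-spike interval is <= ``max_isi_s``.  Returns ordered,
    non-overlapping ``(start_s, end_s, count)`` tuples.
    """
    if max_isi_s <= 0:
        raise ParameterError("max_isi_s must be positive")
    if min_spikes < 2:
        raise ParameterError("min_spikes must be >= 2")
    ts = np.asarray(spiketrain, dtype=np.float64)
    if ts.size < min_spikes:
        return []
    bursts = []
    run_start = 0
    for i in range(1, ts.size + 1):
        if i == ts.size or ts[i] - ts[i - 1] > max_isi_s:
            count = i - run_start
            if count >= min_spikes:
                bursts.append((float(ts[run_start]), float(ts[i - 1]), count))
            run_start = i
    return bursts


def box_summary(values) -> BoxSummary:
    """Box-plot summary: quartiles by linear interpolation, whiskers by the
    1.5*IQR rule clipped to the observed data range."""
    v = np.asarray(values, dtype=np.float64)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise InputError("box_summary requires at least one finite value")
    q1, med, q3 = np.percentile(v, [25, 50, 75])  # linear interpolation
    iqr = q3 - q1
    lo_lim, hi_lim = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_lim) & (v <= hi_lim)]
    whisker_low = float(inside.min())
    whisker_high = float(inside.max())
    outliers = v[(v < whisker_low) | (v > whisker_high)]
    return BoxSummary(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=whisker_low,
        whisker_high=whisker_high,
        outliers=outliers,
        n=int(v.size),
    )


def firing_map(rates: dict, layout: ElectrodeLayout) -> pd.DataFrame:
    """Join per-channel values onto electrode coordinates.

    Returns one row per electrode with columns ``electrode_id, x_um, y_um,
    well_id, channel, value``.  Every channel referenced by the layout's
    channel map must be present in ``rates``.
    """
    chan_to_rate = dict(rates)
    missing = [int(c) for c in layout.channel_map if c not in chan_to_rate]
    if missing:
        raise InputError(f"rates missing for layout channel(s): {missing}")
    return pd.DataFrame(
        {
            "electrode_id": np.arange(layout.n_electrodes),
            "x_um": layout.positions[:, 0],
            "y_um": layout.positions[:, 1],
            "well_id": layout.well_id,
            "channel": layout.channel_map,
            "value": [chan_to_rate[c] for c in layout.channel_map],
        }
    )
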