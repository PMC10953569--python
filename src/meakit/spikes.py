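"""Threshold spike detection, cutout extraction, and PCA spike sorting.

Detection follows the robust median convention: the per-channel noise level
is estimated as ``median(|x|)/0.6745`` (for zero-mean Gaussian noise the
median absolute value equals 0.6745 sigma, so the estimator is unbiased for
sigma and insensitive to the spikes themselves), and the threshold is a
multiple of that estimate — 5 by default, i.e. ``5 * median(|x|)/0.6745``.

Events are defined on the band-pass-filtered trace: a threshold crossing
opens an event window that lasts until the trace re-crosses the threshold;
the timestamp is the extremum within the window, and events on the same
channel closer than the dead time are merged (first extremum wins).

Sorting projects the aligned cutouts onto their top principal components and
clusters in that space with k-means; the cluster count is chosen by the
silhouette score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .errors import InputError, ParameterError
from .io import CutoutSet, Recording, SpikeTrainSet

__all__ = [
    "DetectionConfig",
    "SortResult",
    "estimate_noise",
    "detect_spikes",
    "extract_cutouts",
    "sort_spikes",
]

#: median(|X|) for X ~ N(0, 1); divides the median absolute signal so the
#: estimator returns sigma for pure Gaussian noise.
GAUSS_MEDIAN_ABS = 0.6745


@dataclass(frozen=True)
class DetectionConfig:
    """Parameters of threshold spike detection.

    ``multiplier`` scales the noise estimate into a threshold (default 5);
    ``noise_divisor`` is the Gaussian quantile constant 0.6745; ``polarity``
    selects which deflections count as events; ``dead_time_s`` is the minimum
    same-channel inter-event gap; ``pre_s``/``post_s`` set the cutout window.
    """

    multiplier: float = 5.0
    noise_divisor: float = GAUSS_MEDIAN_ABS
    polarity: str = "negative"
    dead_time_s: float = 0.001
    pre_s: float = 0.001
    post_s: float = 0.002

    def __post_init__(self) -> None:
        if self.multiplier <= 0:
            raise ParameterError(f"multiplier must be positive, got {self.multiplier}")
        if self.noise_divisor <= 0:
            raise ParameterError(f"noise_divisor must be positive, got {self.noise_divisor}")
        if self.polarity not in ("negative", "positive", "both"):
            raise ParameterError(f"unknown polarity {self.polarity!r}")
        if self.dead_time_s < 0:
            raise ParameterError("dead_time_s must be >= 0")
        if self.pre_s <= 0 or self.post_s <= 0:
            raise ParameterError("cutout window pre_s/post_s must be positive")


@dataclass
class SortResult:
    """Unit assignment of sorted spikes.

    ``labels`` holds one unit id in ``0..n_units-1`` per event;
    ``projections`` the per-event principal-component scores.
    """

    labels: np.ndarray
    n_units: int
    projections: np.ndarray
    component_count: int
    notes: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.n_units < 1:
            raise InputError("n_units must be >= 1")
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= self.n_units):
            raise InputError("labels must lie in 0..n_units-1")


def estimate_noise(trace: np.ndarray, divisor: float = GAUSS_MEDIAN_ABS) -> float:
    """Robust noise sigma: ``median(|trace|) / 0.6745`` (µV).

    Scale-equivariant and insensitive to sparse large events, making the
    derived threshold stable in the presence of spikes.
    """
    trace = np.asarray(trace, dtype=np.float64)
    if trace.size == 0:
        raise InputError("cannot estimate noise from an empty trace")
    if not np.all(np.isfinite(trace)):
        raise InputError("trace contains non-finite values")
    return float(np.median(np.abs(trace)) / divisor)


def _crossing_events(trace: np.ndarray, threshold: float, polarity: str) -> np.ndarray:
    """Indices of event extrema: one per contiguous supra-threshold region."""
    if polarity == "negative":
        above = trace < -threshold
        pick = np.argmin
    elif polarity == "positive":
        above = trace > threshold
        pick = np.argmax
    else:  # both
        above = np.abs(trace) > threshold
        trace = np.abs(trace)
        pick = np.argmax
    if not above.any():
        return np.empty(0, dtype=int)
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.concatenate([[0], starts])
    if above[-1]:
        ends = np.concatenate([ends, [len(trace)]])
    return np.array([s + pick(trace[s:e]) for s, e in zip(starts, ends)], dtype=int)


def _enforce_dead_time(idx: np.ndarray, dead_samples: int) -> np.ndarray:
    """Greedy left-to-right dead-time filter: the first extremum wins."""
    if idx.size == 0 or dead_samples <= 0:
        return idx
    kept = [int(idx[0])]
    for i in idx[1:]:
        if i - kept[-1] >= dead_samples:
            kept.append(int(i))
    return np.asarray(kept, dtype=int)


def detect_spikes(
    recording: Recording, config: DetectionConfig | None = None
) -> tuple[SpikeTrainSet, CutoutSet]:
    """Detect spikes on every channel of a (band-pass-filtered) recording.

    The caller is responsible for filtering first; detection on raw traces
    inflates the noise estimate and misses small units.  Channels whose noise
    estimate is zero (flat traces) are skipped with a warning.  Events too
    close to the recording boundary for a full cutout are dropped from both
    the train and the cutout set.
    """
    config = config or DetectionConfig()
    rate = recording.rate
    dead = int(round(config.dead_time_s * rate))
    pre = int(round(config.pre_s * rate))
    post = int(round(config.post_s * rate))

    trains: dict = {}
    snippets, ev_channels, ev_times = [], [], []
    for row, ch in enumerate(recording.channel_ids):
        trace = recording.signal[row]
        if trace.size == 0:
            trains[ch] = np.empty(0)
            continue
        sigma = estimate_noise(trace, config.noise_divisor)
        if sigma == 0.0:
            warnings.warn(f"channel {ch}: flat trace (sigma=0), skipped", stacklevel=2)
            trains[ch] = np.empty(0)
            continue
        threshold = config.multiplier * sigma
        idx = _crossing_events(trace, threshold, config.polarity)
        idx = _enforce_dead_time(idx, dead)
        # drop events without a complete cutout window
        ok = (idx >= pre) & (idx + post < trace.size)
        idx = idx[ok]
        trains[ch] = idx / rate
        for i in idx:
            snippets.append(trace[i - pre : i + post + 1])
            ev_channels.append(row)
            ev_times.append(i / rate)

    duration = max(recording.duration, np.finfo(float).tiny)
    train_set = SpikeTrainSet(trains=trains, duration=duration, channel_ids=recording.channel_ids)
    cutouts = CutoutSet(
        snippets=np.asarray(snippets) if snippets else np.empty((0, pre + post + 1)),
        pre_samples=pre,
        post_samples=post,
        channels=np.asarray(ev_channels, dtype=int),
        timestamps=np.asarray(ev_times),
        rate=rate,
    )
    return train_set, cutouts


def extract_cutouts(
    recording: Recording,
    spiketrains: SpikeTrainSet,
    pre_s: float = 0.001,
    post_s: float = 0.002,
) -> CutoutSet:
    """Extract aligned waveform snippets around given spike timestamps.

    Events closer than ``pre_s`` to the start or ``post_s`` to the end are
    dropped; the number dropped is recorded in ``CutoutSet`` via the
    ``dropped`` attribute set on the returned object.
    """
    rate = recording.rate
    pre = int(round(pre_s * rate))
    post = int(round(post_s * rate))
    row_of = {ch: i for i, ch in enumerate(recording.channel_ids)}
    snippets, ev_channels, ev_times = [], [], []
    dropped = 0
    for ch, ts in spiketrains.trains.items():
        if ch not in row_of:
            raise InputError(f"spike-train channel {ch!r} absent from recording")
        trace = recording.signal[row_of[ch]]
        for t in ts:
            i = int(round(t * rate))
            if i - pre < 0 or i + post >= trace.size:
                dropped += 1
                continue
            snippets.append(trace[i - pre : i + post + 1])
            ev_channels.append(row_of[ch])
            ev_times.append(t)
    out = CutoutSet(
        snippets=np.asarray(snippets) if snippets else np.empty((0, pre + post + 1)),
        pre_samples=pre,
        post_samples=post,
        channels=np.asarray(ev_channels, dtype=int),
        timestamps=np.asarray(ev_times),
        rate=rate,
    )
    out.dropped = dropped
    return out


def sort_spikes(
    cutouts: CutoutSet,
    n_components: int = 2,
    k: int | str = "auto",
    k_max: int = 5,
    seed: int = 0,
) -> SortResult:
    """PCA spike sorting: project cutouts, cluster with k-means.

    With ``k="auto"`` the cluster count is the k in 2..k_max with the best
    silhouette score, falling back to a single unit when the best score is
    below 0.5 (no convincing multi-unit structure).  Deterministic for a
    fixed seed.
    """
    X = cutouts.snippets
    if X.shape[0] < 2 * n_components:
        raise InputError(
            f"need at least {2 * n_components} events for {n_components} "
            f"components, got {X.shape[0]}"
        )
    if np.allclose(X.var(axis=0), 0):
        warnings.warn("zero-variance cutouts: returning a single unit", stacklevel=2)
        return SortResult(
            labels=np.zeros(X.shape[0], dtype=int),
            n_units=1,
            projections=np.zeros((X.shape[0], n_components)),
            component_count=n_components,
            notes=["zero-variance cutouts"],
        )
    pca = PCA(n_components=n_components, random_state=seed)
    proj = pca.fit_transform(X)

    if k == "auto":
        best_k, best_score = 1, -np.inf
        for kk in range(2, min(k_max, X.shape[0] - 1) + 1):
            km = KMeans(n_clusters=kk, n_init=10, random_state=seed).fit(proj)
            if len(np.unique(km.labels_)) < 2:
                continue
            score = silhouette_score(proj, km.labels_)
            if score > best_score:
                best_k, best_score = kk, score
        if best_score < 0.5:
            best_k = 1
        k = best_k
    if k == 1:
        labels = np.zeros(X.shape[0], dtype=int)
    else:
        labels = KMeans(n_clusters=int(k), n_init=10, random_state=seed).fit_predict(proj)
    return SortResult(
        labels=labels,
        n_units=int(len(np.unique(labels))),
        projections=proj,
        component_count=n_components,
    )
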