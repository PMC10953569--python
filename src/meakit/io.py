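"""Core data model and file I/O for extracellular recordings.

A :class:`Recording` holds a channels x samples block of voltages in microvolts
sampled at a fixed rate (30 kHz in typical MEA acquisition).  Spike times live
in a :class:`SpikeTrainSet`; aligned waveform snippets in a :class:`CutoutSet`.

On-disk formats:

* flat channel-interleaved little-endian int16 binary with a JSON sidecar
  (``rate``, ``n_channels``, ``scale``, optional ``t0``) — the dialect common
  acquisition boards export;
* a self-describing HDF5 container (one group per object type, tagged with a
  schema version);
* CSV export of spike timestamps (columns ``channel``, ``time_s``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

from .errors import ConfigError, InputError, MalformedFileError, ParameterError, SchemaError

SCHEMA_VERSION = 1

__all__ = [
    "Recording",
    "SpikeTrainSet",
    "CutoutSet",
    "read_raw_binary",
    "write_raw_binary",
    "write_hdf5",
    "read_hdf5",
    "segment",
    "spiketrains_to_csv",
    "spiketrains_from_csv",
]


@dataclass
class Recording:
    """Multichannel sampled voltage block.

    Parameters
    ----------
    signal:
        ``(n_channels, n_samples)`` array of voltages in microvolts.
    rate:
        Sampling frequency in Hz (must be positive).
    t0:
        Start time of the first sample, in seconds.
    channel_ids:
        Ordered unique channel identifiers; defaults to ``0..n_channels-1``.
    scale:
        Raw-unit -> microvolt conversion factor used when the data were loaded.
    """

    signal: np.ndarray
    rate: float
    t0: float = 0.0
    channel_ids: np.ndarray | None = None
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=np.float64))
        if self.rate <= 0:
            raise ParameterError(f"sampling rate must be positive, got {self.rate}")
        if self.channel_ids is None:
            self.channel_ids = np.arange(self.signal.shape[0])
        else:
            self.channel_ids = np.asarray(self.channel_ids)
            if len(self.channel_ids) != self.signal.shape[0]:
                raise InputError(
                    f"{len(self.channel_ids)} channel ids for "
                    f"{self.signal.shape[0]} signal rows"
                )
            if len(np.unique(self.channel_ids)) != len(self.channel_ids):
                raise InputError("channel_ids must be unique")
        if self.signal.size and not np.all(np.isfinite(self.signal)):
            raise InputError("signal contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.rate

    def times(self) -> np.ndarray:
        """Per-sample time axis in seconds, relative to the recording start."""
        return np.arange(self.n_samples) / self.rate

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Recording):
            return NotImplemented
        return (
            self.rate == other.rate
            and self.t0 == other.t0
            and self.scale == other.scale
            and np.array_equal(self.channel_ids, other.channel_ids)
            and np.array_equal(self.signal, other.signal)
        )


@dataclass
class SpikeTrainSet:
    """Per-channel spike timestamps over a common observation window.

    ``trains`` maps channel id -> strictly increasing array of spike times in
    seconds, all within ``[0, duration]``.
    """

    trains: dict
    duration: float
    channel_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ParameterError(f"duration must be positive, got {self.duration}")
        self.trains = {
            ch: np.asarray(ts, dtype=np.float64) for ch, ts in self.trains.items()
        }
        if self.channel_ids is None:
            self.channel_ids = np.asarray(list(self.trains.keys()))
        for ch, ts in self.trains.items():
            if ts.size and (np.any(np.diff(ts) <= 0)):
                raise InputError(f"channel {ch}: timestamps not strictly increasing")
            if ts.size and (ts[0] < 0 or ts[-1] > self.duration):
                raise InputError(f"channel {ch}: timestamps outside [0, duration]")

    def counts(self) -> dict:
        return {ch: len(ts) for ch, ts in self.trains.items()}

    def n_spikes(self) -> int:
        return sum(len(ts) for ts in self.trains.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpikeTrainSet):
            return NotImplemented
        if self.duration != other.duration:
            return False
        if set(self.trains) != set(other.trains):
            return False
        return all(np.array_equal(self.trains[ch], other.trains[ch]) for ch in self.trains)


@dataclass
class CutoutSet:
    """Aligned waveform snippets around detected events.

    ``snippets`` is ``(n_events, pre_samples + post_samples + 1)``; the
    alignment point (the detection extremum) sits at column ``pre_samples``.
    """

    snippets: np.ndarray
    pre_samples: int
    post_samples: int
    channels: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    timestamps: np.ndarray = field(default_factory=lambda: np.empty(0))
    rate: float = 0.0

    def __post_init__(self) -> None:
        self.snippets = np.atleast_2d(np.asarray(self.snippets, dtype=np.float64))
        expected = self.pre_samples + self.post_samples + 1
        if self.snippets.size and self.snippets.shape[1] != expected:
            raise InputError(
                f"snippet length {self.snippets.shape[1]} != "
                f"pre+post+1 = {expected}"
            )
        self.channels = np.asarray(self.channels, dtype=int)
        self.timestamps = np.asarray(self.timestamps, dtype=np.float64)

    @property
    def n_events(self) -> int:
        return 0 if self.snippets.size == 0 else self.snippets.shape[0]

    def window_times(self) -> np.ndarray:
        """Within-window time axis (s), zero at the alignment sample."""
        n = self.pre_samples + self.post_samples + 1
        return (np.arange(n) - self.pre_samples) / self.rate


# ---------------------------------------------------------------------------
# raw binary dialect
# ---------------------------------------------------------------------------

_REQUIRED_META = ("rate", "n_channels", "scale")


def _load_sidecar(path: Path) -> dict:
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise ConfigError(f"sidecar metadata file not found: {sidecar}")
    with open(sidecar) as fh:
        return json.load(fh)


def read_raw_binary(path, meta: Mapping | None = None) -> Recording:
    """Load a channel-interleaved little-endian int16 file as a Recording.

    ``meta`` must supply ``rate``, ``n_channels`` and ``scale`` (raw -> µV);
    if omitted it is read from the ``<path>.json`` sidecar.  Sample values are
    returned already scaled to microvolts.
    """
    path = Path(path)
    if meta is None:
        meta = _load_sidecar(path)
    missing = [k for k in _REQUIRED_META if k not in meta]
    if missing:
        raise ConfigError(f"metadata missing required field(s): {missing}")
    n_channels = int(meta["n_channels"])
    if n_channels <= 0:
        raise ConfigError(f"n_channels must be positive, got {n_channels}")
    raw = np.fromfile(path, dtype="<i2")
    frame = n_channels  # one int16 per channel per sample
    if raw.size % frame:
        raise MalformedFileError(
            f"{path}: file holds {raw.size} int16 values, expected a multiple "
            f"of {frame} (= {n_channels} channels); "
            f"{raw.size // frame} full frames + {raw.size % frame} stray values"
        )
    n_samples = raw.size // frame
    signal = raw.reshape(n_samples, n_channels).T.astype(np.float64) * float(meta["scale"])
    if n_samples == 0:
        signal = np.zeros((n_channels, 0))
    return Recording(
        signal=signal,
        rate=float(meta["rate"]),
        t0=float(meta.get("t0", 0.0)),
        scale=float(meta["scale"]),
    )


def write_raw_binary(recording: Recording, path) -> Path:
    """Write a Recording in the interleaved int16 + JSON sidecar dialect.

    Voltages are divided by ``recording.scale`` and rounded to int16; a
    round-trip is exact when the original data came from int16 acquisition.
    """
    path = Path(path)
    raw = np.round(recording.signal / recording.scale).astype("<i2")
    raw.T.tofile(path)  # interleave: sample-major frames
    sidecar = {
        "rate": recording.rate,
        "n_channels": recording.n_channels,
        "scale": recording.scale,
        "t0": recording.t0,
    }
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)
    return path


# ---------------------------------------------------------------------------
# HDF5 container
# ---------------------------------------------------------------------------


def write_hdf5(obj, path) -> Path:
    """Serialize a Recording or SpikeTrainSet to the package HDF5 schema."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        if isinstance(obj, Recording):
            g = f.create_group("recording")
            g.create_dataset("signal", data=obj.signal)
            g.attrs["rate"] = obj.rate
            g.attrs["t0"] = obj.t0
            g.attrs["scale"] = obj.scale
            g.create_dataset("channel_ids", data=np.asarray(obj.channel_ids))
        elif isinstance(obj, SpikeTrainSet):
            g = f.create_group("spikes")
            g.attrs["duration"] = obj.duration
            for ch, ts in obj.trains.items():
                g.create_dataset(f"ch_{ch}", data=ts)
        else:
            raise InputError(f"cannot serialize object of type {type(obj).__name__}")
    return path


def read_hdf5(path):
    """Read back an object written by :func:`write_hdf5`."""
    with h5py.File(path, "r") as f:
        version = f.attrs.get("schema_version")
        if version != SCHEMA_VERSION:
            raise SchemaError(f"unknown schema version {version!r} in {path}")
        if "recording" in f:
            g = f["recording"]
            return Recording(
                signal=g["signal"][()],
                rate=float(g.attrs["rate"]),
                t0=float(g.attrs["t0"]),
                channel_ids=g["channel_ids"][()],
                scale=float(g.attrs["scale"]),
            )
        if "spikes" in f:
            g = f["spikes"]
            trains = {}
            for name in g:
                ch = name.removeprefix("ch_")
                key = int(ch) if ch.lstrip("-").isdigit() else ch
                trains[key] = g[name][()]
            return SpikeTrainSet(trains=trains, duration=float(g.attrs["duration"]))
        raise SchemaError(f"{path}: no recognized object group")


# ---------------------------------------------------------------------------
# time segmentation
# ---------------------------------------------------------------------------


def segment(recording: Recording, start_s: float, end_s: float) -> Recording:
    """Extract ``[start_s, end_s)`` from a recording.

    ``t0`` is advanced by ``start_s``.  Sample indices are obtained by
    rounding ``t * rate``, so the returned duration matches ``end - start``
    to within one sample.
    """
    if not (0 <= start_s < end_s <= recording.duration + 0.5 / recording.rate):
        raise ParameterError(
            f"segment bounds [{start_s}, {end_s}] outside "
            f"[0, {recording.duration:.6f}] or inverted"
        )
    i0 = int(round(start_s * recording.rate))
    i1 = min(int(round(end_s * recording.rate)), recording.n_samples)
    return Recording(
        signal=recording.signal[:, i0:i1].copy(),
        rate=recording.rate,
        t0=recording.t0 + start_s,
        channel_ids=recording.channel_ids.copy(),
        scale=recording.scale,
    )


def hourly_segments(recording: Recording, window_s: float = 720.0) -> list[Recording]:
    """Split a long recording into the first ``window_s`` of every hour.

    Mirrors a long-term monitoring protocol sampling the first 12 minutes of
    each hour.  Partial trailing windows are dropped.
    """
    out = []
    t = 0.0
    while t + window_s <= recording.duration + 0.5 / recording.rate:
        out.append(segment(recording, t, t + window_s))
        t += 3600.0
    return out


# ---------------------------------------------------------------------------
# CSV export
# ---------------------------------------------------------------------------


def spiketrains_to_csv(trains: SpikeTrainSet, path) -> Path:
    """Write spike timestamps as tidy CSV (columns: channel, time_s)."""
    rows = [
        (ch, t) for ch, ts in trains.trains.items() for t in ts
    ]
    df = pd.DataFrame(rows, columns=["channel", "time_s"])
    df.to_csv(path, index=False)
    return Path(path)


def spiketrains_from_csv(path, duration: float, channel_ids: Sequence | None = None) -> SpikeTrainSet:
    """Read spike timestamps from the tidy CSV format."""
    df = pd.read_csv(path)
    for col in ("channel", "time_s"):
        if col not in df.columns:
            raise MalformedFileError(f"{path}: missing column {col!r}")
    trains: dict = {}
    for ch, grp in df.groupby("channel"):
        trains[ch] = np.sort(grp["time_s"].to_numpy())
    if channel_ids is not None:
        for ch in channel_ids:
            trains.setdefault(ch, np.empty(0))
    return SpikeTrainSet(trains=trains, duration=duration)
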