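"""Stimulation protocol design: biphasic electrical and optical pulse trains.

Two canonical protocols are supported:

* electrical — trains of biphasic pulses with a positive-to-negative
  transition and no inter-phase gap (e.g. 20 Hz pulses, 400 µs per phase,
  1 s trains);
* optical — LED/laser pulse trains parameterized by rate and duty cycle
  (e.g. 40 Hz at 20% duty, a 1 s train delivered every 5 s for 1 min).

Protocols compile to a :class:`StimTimeline` of non-overlapping timed
intervals which can be validated and exported as CSV/JSON event tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError

__all__ = [
    "PulseTrainSpec",
    "StimTimeline",
    "compile_biphasic",
    "compile_optical",
    "timeline_to_events",
    "validate_timeline",
    "trains_for_duration",
]


@dataclass(frozen=True)
class PulseTrainSpec:
    """Parameters of a repeated pulse train.

    For ``mode="biphasic_electrical"``, ``phase_us`` is the duration of each
    of the two phases and ``amplitude`` the command level in mV.  For
    ``mode="optical"``, ``duty_cycle`` in (0, 1] sets the on-fraction of each
    pulse period.
    """

    pulse_rate_hz: float
    train_duration_s: float
    inter_train_period_s: float
    n_trains: int
    mode: str = "biphasic_electrical"
    phase_us: float = 400.0
    amplitude: float = 700.0
    duty_cycle: float = 0.2

    def __post_init__(self) -> None:
        if self.mode not in ("biphasic_electrical", "optical"):
            raise ParameterError(f"unknown stimulation mode {self.mode!r}")
        if self.pulse_rate_hz <= 0 or self.train_duration_s <= 0:
            raise ParameterError("pulse rate and train duration must be positive")
        if self.pulse_rate_hz * self.train_duration_s < 1:
            raise ParameterError("a train must contain at least one pulse")
        if self.inter_train_period_s < self.train_duration_s:
            raise ParameterError("inter-train period must cover the train duration")
        if self.n_trains < 1:
            raise ParameterError("n_trains must be >= 1")
        if self.mode == "biphasic_electrical":
            period_us = 1e6 / self.pulse_rate_hz
            if 2 * self.phase_us > period_us:
                raise ParameterError(
                    f"two {self.phase_us} µs phases exceed the "
                    f"{period_us:.0f} µs pulse period at {self.pulse_rate_hz} Hz"
                )
        else:
            if not 0 < self.duty_cycle <= 1:
                raise ParameterError(f"duty cycle must be in (0, 1], got {self.duty_cycle}")

    @property
    def pulses_per_train(self) -> int:
        """Whole pulses fitting in one train (partial trailing pulses drop)."""
        return int(np.floor(self.pulse_rate_hz * self.train_duration_s + 1e-9))

    def to_dict(self) -> dict:
        return {
            "pulse_rate_hz": self.pulse_rate_hz,
            "train_duration_s": self.train_duration_s,
            "inter_train_period_s": self.inter_train_period_s,
            "n_trains": self.n_trains,
            "mode": self.mode,
            "phase_us": self.phase_us,
            "amplitude": self.amplitude,
            "duty_cycle": self.duty_cycle,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PulseTrainSpec":
        return cls(**d)


@dataclass
class StimTimeline:
    """Compiled sequence of timed stimulation intervals.

    ``events`` is an ordered list of ``(t_on_s, t_off_s, level)`` with
    non-overlapping intervals inside ``[0, total_duration_s]``.
    """

    events: list
    total_duration_s: float
    target: object = None
    mode: str = ""

    def __post_init__(self) -> None:
        self.events = [(float(a), float(b), float(lv)) for a, b, lv in self.events]

    @property
    def n_events(self) -> int:
        return len(self.events)

    def total_on_time(self) -> float:
        return float(sum(b - a for a, b, _ in self.events))


def trains_for_duration(total_s: float, inter_train_period_s: float) -> int:
    """Whole trains fitting in a protocol of a given total length
    (e.g. a 1 s train every 5 s for 60 s -> 12 trains)."""
    if inter_train_period_s <= 0:
        raise ParameterError("inter-train period must be positive")
    return int(np.floor(total_s / inter_train_period_s + 1e-9))


def compile_biphasic(spec: PulseTrainSpec, target=None) -> StimTimeline:
    """Compile an electrical biphasic protocol into a timeline.

    Each pulse is a positive phase immediately followed by a negative phase
    (levels +A then -A), both of ``phase_us``; pulses are anchored at
    multiples of ``1/pulse_rate`` from the train start.
    """
    if spec.mode != "biphasic_electrical":
        raise ParameterError("compile_biphasic requires a biphasic_electrical spec")
    phase_s = spec.phase_us * 1e-6
    period = 1.0 / spec.pulse_rate_hz
    events = []
    for train in range(spec.n_trains):
        t_train = train * spec.inter_train_period_s
        for p in range(spec.pulses_per_train):
            t = t_train + p * period
            events.append((t, t + phase_s, +spec.amplitude))
            events.append((t + phase_s, t + 2 * phase_s, -spec.amplitude))
    total = (spec.n_trains - 1) * spec.inter_train_period_s + spec.train_duration_s
    return StimTimeline(events=events, total_duration_s=total, target=target, mode=spec.mode)


def compile_optical(spec: PulseTrainSpec, target=None) -> StimTimeline:
    """Compile an optical duty-cycled protocol into a timeline.

    Within each train, pulses repeat at ``pulse_rate`` with on-time
    ``duty_cycle / pulse_rate`` each, so the total on-time of a train is
    ``duty_cycle * train_duration``.
    """
    if spec.mode != "optical":
        raise ParameterError("compile_optical requires an optical spec")
    period = 1.0 / spec.pulse_rate_hz
    on_time = spec.duty_cycle * period
    events = []
    for train in range(spec.n_trains):
        t_train = train * spec.inter_train_period_s
        for p in range(spec.pulses_per_train):
            t = t_train + p * period
            events.append((t, t + on_time, 1.0))
    total = (spec.n_trains - 1) * spec.inter_train_period_s + spec.train_duration_s
    return StimTimeline(events=events, total_duration_s=total, target=target, mode=spec.mode)


def timeline_to_events(timeline: StimTimeline) -> pd.DataFrame:
    """Event table with columns ``t_on_s, t_off_s, level``."""
    return pd.DataFrame(timeline.events, columns=["t_on_s", "t_off_s", "level"])


def validate_timeline(timeline: StimTimeline, tol: float = 1e-12) -> dict:
    """Check ordering, non-overlap and bounds; returns a violation report."""
    violations = []
    prev_off = -np.inf
    for i, (a, b, _) in enumerate(timeline.events):
        if b <= a:
            violations.append(f"event {i}: empty or inverted interval ({a}, {b})")
        if a < prev_off - tol:
            violations.append(f"event {i}: overlaps previous (starts {a} < {prev_off})")
        if a < -tol or b > timeline.total_duration_s + tol:
            violations.append(f"event {i}: outside [0, {timeline.total_duration_s}]")
        prev_off = max(prev_off, b)
    return {"ok": not violations, "n_events": timeline.n_events, "violations": violations}


def save_events(timeline: StimTimeline, path) -> Path:
    """Export the event table as CSV (or JSON when the path ends in .json)."""
    path = Path(path)
    df = timeline_to_events(timeline)
    if path.suffix.lower() == ".json":
        df.to_json(path, orient="records")
    else:
        df.to_csv(path, index=False)
    return path
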