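"""Domain types for sonar pulse-event data and the event-table format.

A recording session is split into fixed-length *epochs* (default 10 s).
Within an epoch each emitter (bat) contributes a :class:`PulseTrain` of
sorted pulse onsets with per-pulse durations.  Epochs may carry an optional
:class:`StimulusSchedule` describing a periodic noise stimulus.

On-disk format: UTF-8 tab-separated text with header
``epoch_id<TAB>bat_id<TAB>onset_s<TAB>duration_ms``.  Onsets are
epoch-relative seconds in the half-open window ``[0, T)``; durations are
milliseconds.  Files are validated on read and never silently repaired.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PulseTrain",
    "StimulusSchedule",
    "EpochRecording",
    "EventTableError",
    "read_events",
    "write_events",
]

EVENT_COLUMNS = ("epoch_id", "bat_id", "onset_s", "duration_ms")

#: Pulse durations of free-tailed-bat sonar pulses in these conditions
#: typically span 4-8 ms; used as the default sampling range.
DEFAULT_DURATION_RANGE_MS = (4.0, 8.0)


class EventTableError(ValueError):
    """Raised when an event table or a domain invariant is invalid."""


@dataclass
class PulseTrain:
    """One emitter's pulse onsets (seconds) and durations (ms) in an epoch.

    Invariants: onsets strictly increasing, non-negative; durations positive
    and the same length as onsets.
    """

    emitter_id: str
    onsets: np.ndarray
    durations_ms: np.ndarray

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.durations_ms = np.asarray(self.durations_ms, dtype=float)
        if self.onsets.ndim != 1 or self.durations_ms.ndim != 1:
            raise EventTableError("onsets and durations must be 1-D")
        if len(self.onsets) != len(self.durations_ms):
            raise EventTableError(
                f"train {self.emitter_id!r}: {len(self.onsets)} onsets but "
                f"{len(self.durations_ms)} durations"
            )
        if len(self.onsets):
            if np.any(self.onsets < 0):
                raise EventTableError(f"train {self.emitter_id!r}: negative onset")
            if np.any(np.diff(self.onsets) <= 0):
                raise EventTableError(
                    f"train {self.emitter_id!r}: onsets not strictly increasing"
                )
            if np.any(self.durations_ms <= 0):
                raise EventTableError(f"train {self.emitter_id!r}: non-positive duration")

    def __len__(self) -> int:
        return len(self.onsets)

    def rate(self, duration_T: float) -> float:
        """Mean emission rate over the epoch, pulses per second."""
        return len(self.onsets) / duration_T


@dataclass
class StimulusSchedule:
    """Periodic noise-burst stimulus tiling an epoch.

    ``intervals`` is an ordered list of ``(start_s, end_s, state)`` with
    ``state`` in ``{"noise", "silence"}`` tiling ``[0, T]`` without gaps.
    ``burst_ms`` / ``silent_ms`` record the generating period.
    """

    intervals: list[tuple[float, float, str]]
    burst_ms: float
    silent_ms: float

    def __post_init__(self) -> None:
        prev_end = None
        for start, end, state in self.intervals:
            if state not in ("noise", "silence"):
                raise EventTableError(f"unknown stimulus state {state!r}")
            if not start < end:
                raise EventTableError("stimulus interval must have start < end")
            if prev_end is not None and not np.isclose(start, prev_end):
                raise EventTableError("stimulus intervals must tile without gaps")
            prev_end = end

    @property
    def duty_cycle(self) -> float:
        """Fraction of the period the noise is on: burst/(burst+silent)."""
        total = self.burst_ms + self.silent_ms
        if total <= 0:
            raise EventTableError("burst_ms + silent_ms must be positive")
        return self.burst_ms / total

    @property
    def duration_T(self) -> float:
        return self.intervals[-1][1] if self.intervals else 0.0

    def state_at(self, t: float) -> str:
        """Stimulus state ('noise'/'silence') at time t (seconds)."""
        for start, end, state in self.intervals:
            if start <= t < end:
                return state
        return self.intervals[-1][2] if self.intervals else "silence"

    def time_in_state(self, state: str) -> float:
        """Total seconds the schedule spends in the given state."""
        return sum(end - start for start, end, s in self.intervals if s == state)

    def noise_onsets(self) -> np.ndarray:
        """Start times (s) of every noise burst, in order."""
        return np.array(
            [start for start, _end, s in self.intervals if s == "noise"], dtype=float
        )


@dataclass
class EpochRecording:
    """A fixed-duration epoch holding one or more pulse trains."""

    epoch_id: str
    duration_T: float = 10.0
    trains: list[PulseTrain] = field(default_factory=list)
    stimulus: StimulusSchedule | None = None

    def __post_init__(self) -> None:
        if self.duration_T <= 0:
            raise EventTableError(f"epoch {self.epoch_id!r}: duration_T must be > 0")
        ids = [t.emitter_id for t in self.trains]
        if len(ids) != len(set(ids)):
            raise EventTableError(f"epoch {self.epoch_id!r}: duplicate emitter ids")
        for train in self.trains:
            if len(train) and train.onsets[-1] >= self.duration_T:
                raise EventTableError(
                    f"epoch {self.epoch_id!r}, train {train.emitter_id!r}: "
                    f"onset beyond epoch duration {self.duration_T}"
                )

    @property
    def n_bats(self) -> int:
        return len(self.trains)

    @property
    def total_pulses(self) -> int:
        return sum(len(t) for t in self.trains)

    def train(self, emitter_id: str) -> PulseTrain:
        for t in self.trains:
            if t.emitter_id == emitter_id:
                return t
        raise KeyError(emitter_id)


def read_events(path) -> list[EpochRecording]:
    """Read an event table (TSV) into a list of :class:`EpochRecording`.

    Rows may appear in any order; events are grouped by epoch then emitter
    and onsets sorted.  Epochs are returned in first-appearance order.
    Every domain invariant is re-validated; a violating file is rejected
    with the offending row number, never repaired.

    The epoch duration is taken as 10 s unless a pulse onset exceeds it, in
    which case the duration is the smallest multiple of 10 s containing all
    onsets (the format does not carry T explicitly).
    """
    df = pd.read_csv(path, sep="\t", dtype={"epoch_id": str, "bat_id": str})
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise EventTableError(f"{path}: missing column(s) {missing}")
    for col in ("onset_s", "duration_ms"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[numeric.isna() & df[col].notna()]
        if len(bad):
            # +2: 1-based data rows after the header line
            raise EventTableError(f"{path}: non-numeric {col} at row {bad[0] + 2}")
        if numeric.isna().any():
            row = int(df.index[numeric.isna()][0]) + 2
            raise EventTableError(f"{path}: missing {col} at row {row}")
        df[col] = numeric
    neg = df.index[df["onset_s"] < 0]
    if len(neg):
        raise EventTableError(f"{path}: negative onset at row {neg[0] + 2}")
    dup = df.duplicated(subset=["epoch_id", "bat_id", "onset_s"])
    if dup.any():
        row = int(df.index[dup][0]) + 2
        raise EventTableError(f"{path}: duplicate (epoch, bat, onset) at row {row}")

    epochs: list[EpochRecording] = []
    for epoch_id in df["epoch_id"].drop_duplicates():
        sub = df[df["epoch_id"] == epoch_id]
        max_onset = sub["onset_s"].max() if len(sub) else 0.0
        duration_T = 10.0 * max(1.0, np.ceil((max_onset + 1e-9) / 10.0))
        trains = []
        for bat_id in sub["bat_id"].drop_duplicates():
            rows = sub[sub["bat_id"] == bat_id].sort_values("onset_s")
            trains.append(
                PulseTrain(
                    emitter_id=str(bat_id),
                    onsets=rows["onset_s"].to_numpy(),
                    durations_ms=rows["duration_ms"].to_numpy(),
                )
            )
        epochs.append(
            EpochRecording(epoch_id=str(epoch_id), duration_T=duration_T, trains=trains)
        )
    return epochs


def write_events(epochs: Iterable[EpochRecording], path) -> None:
    """Write epochs as an event table (TSV) in deterministic row order.

    Rows are ordered by (epoch appearance, emitter, onset); onsets are
    printed with 9 decimal places so a round trip reproduces them exactly
    at double precision for the time scales involved.
    """
    records = []
    for epoch in epochs:
        for train in sorted(epoch.trains, key=lambda t: t.emitter_id):
            for onset, dur in zip(train.onsets, train.durations_ms):
                records.append((epoch.epoch_id, train.emitter_id, onset, dur))
    df = pd.DataFrame.from_records(records, columns=EVENT_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.9f")


def epochs_equal(a: Sequence[EpochRecording], b: Sequence[EpochRecording],
                 atol: float = 1e-8) -> bool:
    """True when two epoch lists hold the same events to within atol."""
    if len(a) != len(b):
        return False
    for ea, eb in zip(a, b):
        if ea.epoch_id != eb.epoch_id or ea.n_bats != eb.n_bats:
            return False
        for ta in ea.trains:
            try:
                tb = eb.train(ta.emitter_id)
            except KeyError:
                return False
            if len(ta) != len(tb):
                return False
            if not np.allclose(ta.onsets, tb.onsets, atol=atol):
                return False
            if not np.allclose(ta.durations_ms, tb.durations_ms, atol=atol):
                return False
    return True
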