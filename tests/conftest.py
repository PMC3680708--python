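"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from sonarchannel.events import EpochRecording, PulseTrain


def make_train(emitter_id: str, onsets, durations_ms=None) -> PulseTrain:
    onsets = np.asarray(onsets, dtype=float)
    if durations_ms is None:
        durations_ms = np.full(len(onsets), 5.0)
    return PulseTrain(emitter_id=emitter_id, onsets=onsets,
                      durations_ms=durations_ms)


def random_epoch(rng: np.random.Generator, n_bats: int = 2,
                 mean_pulses: float = 20.0, T: float = 10.0,
                 epoch_id: str = "rand") -> EpochRecording:
    """A random multi-bat epoch with uniformly scattered onsets."""
    trains = []
    for b in range(n_bats):
        k = rng.poisson(mean_pulses)
        onsets = np.sort(rng.uniform(0, T, size=k))
        onsets = np.unique(onsets)  # strict monotonicity
        trains.append(make_train(f"bat{b}", onsets,
                                 rng.uniform(4, 8, size=len(onsets))))
    return EpochRecording(epoch_id=epoch_id, duration_T=T, trains=trains)


def brute_force_overlap_pairs(epoch: EpochRecording, tau_ms: float,
                              cross_only: bool = True) -> set[frozenset]:
    """O(P^2) all-pairs enumeration of onset overlaps, as canonical sets.

    Independent of the sweep implementation: every unordered pulse pair is
    tested for |onset difference| < tau.  Each event is represented as a
    frozenset of (emitter, onset) so ordering conventions cannot matter.
    """
    pulses = [(t.emitter_id, float(o)) for t in epoch.trains for o in t.onsets]
    tau = tau_ms / 1000.0
    out = set()
    for i in range(len(pulses)):
        for j in range(i + 1, len(pulses)):
            ei, oi = pulses[i]
            ej, oj = pulses[j]
            if cross_only and ei == ej:
                continue
            if abs(oi - oj) < tau:
                out.add(frozenset([(ei, oi), (ej, oj)]))
    return out


def sweep_overlap_pairs(epoch: EpochRecording, tau_ms: float,
                        cross_only: bool = True) -> set[frozenset]:
    """The package detector's events in the same canonical representation."""
    from sonarchannel.interference import detect_overlaps

    return {
        frozenset([(ev.emitter_a, ev.onset_a), (ev.emitter_b, ev.onset_b)])
        for ev in detect_overlaps(epoch, tau_ms=tau_ms, cross_only=cross_only)
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
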