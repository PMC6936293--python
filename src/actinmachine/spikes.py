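"""Spike detection and coincidence grouping of electrode potential traces.

A spike — a transient peak of the excited-voxel count at an electrode —
represents logical True.  Two spikes fewer than six iterations apart are
treated as happening at the same moment; this coincidence window applies
both when merging peaks within one trace and when aligning spikes across
electrodes or across runs.

The potential is an integer count, so detection is simple: any local
maximum of the series with amplitude >= the threshold (default 1, i.e.
any non-zero peak) is a spike; on a plateau of equal values the first
step is taken as the spike time.  Peaks closer than the window are merged
keeping the earlier time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .electrodes import PotentialTrace

__all__ = [
    "COINCIDENCE_WINDOW",
    "SpikeTrain",
    "CoincidenceGroup",
    "detect_spikes",
    "merge_spike_times",
    "spike_trains",
    "group_coincident",
]

#: Spikes fewer than this many iterations apart count as simultaneous.
COINCIDENCE_WINDOW = 6


@dataclass(frozen=True)
class SpikeTrain:
    """Strictly increasing spike times (integer steps) for one electrode."""

    electrode: str
    times: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValueError("spike times must be strictly increasing")


@dataclass(frozen=True)
class CoincidenceGroup:
    """Spikes treated as one simultaneous event.

    ``time`` is the representative (earliest member) time; ``members`` are
    (electrode, time) pairs.
    """

    time: int
    members: tuple[tuple[str, int], ...]

    def electrodes(self) -> frozenset[str]:
        return frozenset(e for e, _ in self.members)


def merge_spike_times(times: Sequence[int], window: int = COINCIDENCE_WINDOW) -> tuple[int, ...]:
    """Greedily merge sorted spike times closer than ``window``, keeping the earlier."""
    if window < 1:
        raise ValueError("window must be >= 1")
    merged: list[int] = []
    for t in sorted(times):
        if not merged or t - merged[-1] >= window:
            merged.append(int(t))
    return tuple(merged)


def detect_spikes(
    values: Sequence[float] | np.ndarray,
    amp_threshold: float = 1.0,
    window: int = COINCIDENCE_WINDOW,
    t0: int = 1,
) -> tuple[int, ...]:
    """Spike times of a potential series recorded at t = t0, t0+1, ...

    A spike is a local maximum with value >= ``amp_threshold``; series ends
    count as descents, so a peak touching the boundary is kept.  Plateaus
    spike at their first step.  Peaks closer than ``window`` are merged.
    """
    if amp_threshold < 0:
        raise ValueError("amplitude threshold must be non-negative")
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError("expected a 1D series")
    # run-length encode into (start_index, value)
    runs: list[tuple[int, float]] = []
    for idx, val in enumerate(v):
        if not runs or runs[-1][1] != val:
            runs.append((idx, float(val)))
    peaks = []
    for n, (start, val) in enumerate(runs):
        prev = runs[n - 1][1] if n > 0 else -np.inf
        nxt = runs[n + 1][1] if n + 1 < len(runs) else -np.inf
        if val >= amp_threshold and val > prev and val > nxt:
            peaks.append(start + t0)
    return merge_spike_times(peaks, window)


def spike_trains(
    trace: PotentialTrace,
    amp_threshold: float = 1.0,
    window: int = COINCIDENCE_WINDOW,
) -> list[SpikeTrain]:
    """Detect spikes on every electrode column of a potential trace."""
    return [
        SpikeTrain(label, detect_spikes(trace.column(c), amp_threshold, window))
        for c, label in enumerate(trace.labels)
    ]


def group_coincident(
    trains: Iterable[SpikeTrain], window: int = COINCIDENCE_WINDOW
) -> list[CoincidenceGroup]:
    """Single-linkage grouping of all spikes on the shared time axis.

    Spikes whose consecutive gap is < ``window`` chain into one group
    (transitive closure); groups are ordered by representative time and
    partition the spike set.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    events = sorted(
        ((t, train.electrode) for train in trains for t in train.times),
        key=lambda e: (e[0], e[1]),
    )
    groups: list[CoincidenceGroup] = []
    current: list[tuple[str, int]] = []
    for t, electrode in events:
        if current and t - current[-1][1] >= window:
            groups.append(CoincidenceGroup(current[0][1], tuple(current)))
            current = []
        current.append((electrode, t))
    if current:
        groups.append(CoincidenceGroup(current[0][1], tuple(current)))
    return groups
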