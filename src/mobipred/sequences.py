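"""Symbolic movement sequences: next time-bin and next place representations.

The *next time-bin* sequence samples the visit history on a regular clock:
one symbol per interval of width ``delta_t`` giving the stay-region where the
user spent the most time during that interval (majority-time rule), with a
null for intervals without any recorded dwell.  The *next place* sequence
drops the clock entirely and keeps only transitions: region ids in visit
order with consecutive repeats collapsed.

Rules applied per bin:
  1. the region with the largest dwell overlap wins;
  2. ties go to the region visited more often over the whole visit history;
  3. remaining ties go to the smallest region id (deterministic);
  4. a bin with zero overlap is null.

Bins are anchored at the first visit's start floored to a whole multiple of
``delta_t`` from midnight UTC of that day, so hour-wide bins align with the
hour-based definition of the missing-record fraction q.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np

from ._util import DAY_S, HOUR_S, as_seconds, epoch_seconds, from_epoch_seconds
from .regions import RegionAssignment
from .staypoints import StayPointSequence, Trajectory


@dataclass
class RegionVisitSequence:
    """Time-ordered (region id, start, end) visits of one user."""

    user_id: str
    visits: list[tuple[int, np.datetime64, np.datetime64]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.visits)


@dataclass
class TimeBinSequence:
    """Next time-bin symbols (region ids, None for empty bins) on a regular clock."""

    user_id: str
    delta_t: float  # bin width, seconds
    origin: np.datetime64  # start of bin 0
    symbols: list[int | None] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.symbols)

    def bin_start(self, k: int) -> np.datetime64:
        return from_epoch_seconds(epoch_seconds(self.origin) + k * self.delta_t)


@dataclass
class PlaceSequence:
    """Next place symbols: visit-ordered region ids, consecutive repeats removed."""

    user_id: str
    symbols: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.symbols)


def visits_from_assignment(
    staypoints: StayPointSequence, assignment: RegionAssignment
) -> RegionVisitSequence:
    """Relabel a stay-point sequence with its region ids to get a visit history."""
    if len(staypoints) != len(assignment.labels):
        raise ValueError("assignment does not match the stay-point sequence")
    visits = [
        (int(lab), sp.start, sp.end)
        for sp, lab in zip(staypoints, assignment.labels)
    ]
    return RegionVisitSequence(user_id=staypoints.user_id, visits=visits)


def build_time_bin_sequence(visits: RegionVisitSequence, delta_t) -> TimeBinSequence:
    """Aggregate a visit history into a next time-bin sequence of width ``delta_t``."""
    dt = as_seconds(delta_t)
    if dt <= 0:
        raise ValueError("delta_t must be > 0")
    if len(visits) == 0:
        raise ValueError("empty visit sequence")

    starts = epoch_seconds(np.array([v[1] for v in visits.visits]))
    ends = epoch_seconds(np.array([v[2] for v in visits.visits]))
    regions = [int(v[0]) for v in visits.visits]

    midnight = math.floor(starts[0] / DAY_S) * DAY_S
    origin = midnight + math.floor((starts[0] - midnight) / dt) * dt
    span = ends.max() - origin
    n_bins = max(1, math.ceil(span / dt)) if span > 0 else 1

    # dwell overlap per (bin, region)
    overlap: dict[int, dict[int, float]] = defaultdict(lambda: defaultdict(float))
    for reg, s, e in zip(regions, starts, ends):
        k0 = int(math.floor((s - origin) / dt))
        k1 = min(int(math.floor((e - origin) / dt)), n_bins - 1)
        for k in range(max(k0, 0), k1 + 1):
            lo, hi = origin + k * dt, origin + (k + 1) * dt
            ov = min(e, hi) - max(s, lo)
            if ov > 0 or (s == e and lo <= s < hi):
                overlap[k][reg] += max(ov, 0.0)

    visit_counts = Counter(regions)
    symbols: list[int | None] = []
    for k in range(n_bins):
        cand = overlap.get(k)
        if not cand:
            symbols.append(None)
            continue
        # majority time, then overall visit frequency, then smallest id
        best = min(cand.items(), key=lambda kv: (-kv[1], -visit_counts[kv[0]], kv[0]))
        symbols.append(best[0])
    return TimeBinSequence(
        user_id=visits.user_id, delta_t=dt, origin=from_epoch_seconds(origin), symbols=symbols
    )


def build_next_place_sequence(visits: RegionVisitSequence) -> PlaceSequence:
    """Collapse consecutive repeated regions out of a visit history."""
    if len(visits) == 0:
        raise ValueError("empty visit sequence")
    symbols: list[int] = []
    for reg, *_ in visits.visits:
        if not symbols or symbols[-1] != reg:
            symbols.append(int(reg))
    return PlaceSequence(user_id=visits.user_id, symbols=symbols)


def compute_q(seq: TimeBinSequence) -> float:
    """Fraction of null (empty) bins."""
    if len(seq) == 0:
        raise ValueError("zero-length sequence")
    return sum(1 for s in seq.symbols if s is None) / len(seq)


def sequence_stats(seq: TimeBinSequence | PlaceSequence) -> tuple[int, int, int]:
    """(n_records, n_regions, n_self_transitions) of a symbolic sequence.

    Nulls are not records, do not count as regions, and break adjacency for
    the self-transition count (a gap is no evidence the user stayed put).
    """
    syms = seq.symbols
    n_records = sum(1 for s in syms if s is not None)
    n_regions = len({s for s in syms if s is not None})
    self_tr = sum(
        1
        for a, b in zip(syms, syms[1:])
        if a is not None and b is not None and a == b
    )
    return n_records, n_regions, self_tr


def hour_level_q(trajectory: Trajectory) -> float:
    """Fraction of hour-long windows without any recorded point."""
    if len(trajectory) == 0:
        return 1.0
    ts = epoch_seconds(trajectory.t)
    h0 = math.floor(ts[0] / HOUR_S)
    h1 = math.floor(ts[-1] / HOUR_S)
    n_hours = h1 - h0 + 1
    occupied = len(np.unique(np.floor(ts / HOUR_S).astype(np.int64)))
    return 1.0 - occupied / n_hours


def observation_span_days(trajectory: Trajectory) -> float:
    """Span between the first and last recorded point, in days."""
    if len(trajectory) < 2:
        return 0.0
    ts = epoch_seconds(trajectory.t)
    return float((ts[-1] - ts[0]) / DAY_S)


def filter_users(
    population: dict[str, Trajectory], q_max: float = 0.15, d_min_days: float = 28.0
) -> dict[str, Trajectory]:
    """Retain users with hour-level missingness q <= q_max and span >= d_min_days."""
    return {
        uid: traj
        for uid, traj in population.items()
        if hour_level_q(traj) <= q_max and observation_span_days(traj) >= d_min_days
    }


def delta_t_sweep_values() -> list[float]:
    """The temporal-resolution sweep, in seconds (5 min up to 144 h).

    Minute values 5, 10, 15, 30, 45, 60 and hour values 6, 12, 24, 48, 72,
    144; the duplicated 60 min / 1 h entry appears once.
    """
    minutes = [5, 10, 15, 30, 45, 60]
    hours = [6, 12, 24, 48, 72, 144]
    return [m * 60.0 for m in minutes] + [h * 3600.0 for h in hours]
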