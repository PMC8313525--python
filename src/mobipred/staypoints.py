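"""Stay-point detection: extract dwell episodes from raw point trajectories.

A stay-point is a maximal run of consecutive trajectory points that all lie
within a distance ``delta`` of the first point of the run and whose elapsed
time exceeds ``tau``.  The scan walks the trajectory once: points are
accumulated while they stay within ``delta`` of the run's first point; on the
first violation the accumulated run is emitted as a stay-point if it lasted
longer than ``tau`` (otherwise discarded), and the scan restarts at the
violating point.  The trailing run at end-of-data is tested the same way, so
a final overnight dwell is not lost.

Distances are planar Euclidean in metres; project lon/lat inputs first
(see :mod:`mobipred.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._util import as_seconds, epoch_seconds


@dataclass
class Trajectory:
    """One user's time-ordered positioned points (x, y in metres, t timestamps)."""

    user_id: str
    x: np.ndarray
    y: np.ndarray
    t: np.ndarray  # datetime64, strictly increasing

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.t = np.asarray(self.t)
        if not (len(self.x) == len(self.y) == len(self.t)):
            raise ValueError("x, y, t must have equal length")
        if len(self.t) and not np.issubdtype(self.t.dtype, np.datetime64):
            raise ValueError("t must be a datetime64 array")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("coordinates must be finite")
        if len(self.t) > 1 and not (np.diff(self.t.astype("datetime64[ns]")) > np.timedelta64(0)).all():
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.x)


@dataclass(frozen=True)
class StayPoint:
    """A dwell episode: centroid of its member points plus the visit interval."""

    x: float
    y: float
    start: np.datetime64
    end: np.datetime64
    n_member_points: int

    @property
    def duration(self) -> float:
        """Dwell duration in seconds."""
        return float(epoch_seconds(self.end) - epoch_seconds(self.start))


@dataclass
class StayPointSequence:
    """Time-ordered stay-points of one user, with the thresholds used."""

    user_id: str
    staypoints: list[StayPoint] = field(default_factory=list)
    delta: float = 300.0
    tau: float = 600.0

    def __len__(self) -> int:
        return len(self.staypoints)

    def __iter__(self):
        return iter(self.staypoints)

    def coords(self) -> np.ndarray:
        """(n, 2) array of stay-point centroids."""
        return np.array([[s.x, s.y] for s in self.staypoints], dtype=float).reshape(-1, 2)


def detect_staypoints(trajectory: Trajectory, delta: float = 300.0, tau=600.0) -> StayPointSequence:
    """Run the distance/time threshold scan over a trajectory.

    Parameters
    ----------
    trajectory
        Time-ordered points; an empty trajectory yields an empty sequence.
    delta
        Distance threshold in metres (default 300 m). A point joins the
        current run while its distance to the run's *first* point is < delta.
    tau
        Minimum dwell time (default 10 min); a run is emitted only when its
        elapsed time is strictly greater than tau. Accepts seconds or a
        timedelta.
    """
    tau_s = as_seconds(tau)
    if delta <= 0 or tau_s < 0:
        raise ValueError("delta must be > 0 and tau >= 0")
    n = len(trajectory)
    out = StayPointSequence(user_id=trajectory.user_id, delta=float(delta), tau=tau_s)
    if n == 0:
        return out

    x, y = trajectory.x, trajectory.y
    ts = epoch_seconds(trajectory.t)

    i = 0
    block = 512
    while i < n:
        # accumulate while within delta of the run's first point
        j = i + 1
        while j < n:
            k = min(n, j + block)
            bad = np.flatnonzero(np.hypot(x[j:k] - x[i], y[j:k] - y[i]) >= delta)
            if bad.size:
                j += int(bad[0])
                break
            j = k
        last = j - 1
        if ts[last] - ts[i] > tau_s:
            out.staypoints.append(
                StayPoint(
                    x=float(x[i : j].mean()),
                    y=float(y[i : j].mean()),
                    start=trajectory.t[i],
                    end=trajectory.t[last],
                    n_member_points=j - i,
                )
            )
        if j >= n:
            break
        i = j  # restart at the first point that violated delta
    return out
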