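"""Synthetic multi-day trajectories with known ground truth.

The generator emulates the kind of data the analysis pipeline targets:
individuals who shuttle between a small set of repeatedly visited anchor
locations (home, work, errands) over four weeks, recorded by a GNSS-like
device at a fixed sampling interval with isotropic positional noise, and
with whole hour-long windows of records missing.

The visit schedule is a Markov chain over anchors: a dwell of random
(shifted-exponential) duration at the current anchor, then a straight-line
travel leg at constant speed to the next anchor drawn from the transition
matrix.  Dwell durations have a floor so that every visit is long enough to
be detectable as a stay-point; travel points exist precisely so the
stay-point scan has something to discard.  Missingness is injected by
emptying whole hour-long windows because record completeness q is defined
over hour-long intervals.

Coordinates are generated directly in a planar metric frame (metres).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._util import (
    DAY_S,
    HOUR_S,
    check_row_stochastic,
    from_epoch_seconds,
    is_irreducible,
    stationary_distribution,
)
from .staypoints import Trajectory

#: all synthetic clocks start here (midnight UTC)
T0_EPOCH_S = 1_583_020_800  # 2020-03-01T00:00:00Z


@dataclass
class MobilityModelConfig:
    """Parameters of the anchor-based mobility simulator.

    Defaults mirror the study conditions the pipeline is meant for: 28-day
    trajectories sampled every 60 s with ~4% of hour-windows missing.
    """

    n_anchors: int
    anchor_coords: np.ndarray  # (n_anchors, 2), metres
    transition_matrix: np.ndarray  # row-stochastic over anchors
    dwell_mean_per_anchor: np.ndarray  # seconds, per anchor
    travel_speed: float = 10.0  # m/s
    sampling_interval: float = 60.0  # s
    gnss_noise_sigma: float = 10.0  # m
    duration_days: int = 28
    missing_fraction_target: float = 0.04
    seed: int = 0
    dwell_min: float = 900.0  # s; floor so every visit is detectable

    def __post_init__(self) -> None:
        self.anchor_coords = np.asarray(self.anchor_coords, dtype=float).reshape(-1, 2)
        self.dwell_mean_per_anchor = np.broadcast_to(
            np.asarray(self.dwell_mean_per_anchor, dtype=float), (self.n_anchors,)
        ).copy()
        self.transition_matrix = check_row_stochastic(self.transition_matrix)

    def validate(self) -> None:
        if len(self.anchor_coords) != self.n_anchors:
            raise ValueError("anchor_coords must have n_anchors rows")
        if self.transition_matrix.shape != (self.n_anchors, self.n_anchors):
            raise ValueError("transition matrix shape must match n_anchors")
        if self.duration_days < 1:
            raise ValueError("duration_days must be >= 1")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be > 0")
        if self.gnss_noise_sigma < 0:
            raise ValueError("gnss_noise_sigma must be >= 0")
        if not 0 <= self.missing_fraction_target < 1:
            raise ValueError("missing_fraction_target must be in [0, 1)")
        if self.travel_speed <= 0:
            raise ValueError("travel_speed must be > 0")
        if self.n_anchors > 1 and self.gnss_noise_sigma > 0:
            from scipy.spatial.distance import pdist

            if pdist(self.anchor_coords).min() < 2 * self.gnss_noise_sigma:
                warnings.warn(
                    "anchors closer than 2x GNSS noise sigma: ground truth may be "
                    "unrecoverable",
                    RuntimeWarning,
                    stacklevel=2,
                )


@dataclass
class GroundTruth:
    """The true visit schedule behind a generated trajectory."""

    true_visit_sequence: list[tuple[int, np.datetime64, np.datetime64]] = field(
        default_factory=list
    )
    anchor_coords: np.ndarray | None = None


def random_config(
    seed: int,
    n_anchors: int | None = None,
    extent: float = 8000.0,
    min_separation: float = 800.0,
    **overrides,
) -> MobilityModelConfig:
    """Draw a plausible per-user configuration.

    Anchors are scattered over an ``extent`` x ``extent`` square, at least
    ``min_separation`` apart; one anchor plays the role of home (long dwells,
    frequently returned to), the rest get dwell means between 1 and 4 hours.
    """
    rng = np.random.default_rng(seed)
    if n_anchors is None:
        n_anchors = int(rng.integers(5, 9))
    coords: list[np.ndarray] = []
    while len(coords) < n_anchors:
        cand = rng.uniform(0, extent, size=2)
        if all(np.hypot(*(cand - c)) >= min_separation for c in coords):
            coords.append(cand)
    if n_anchors == 1:
        P = np.ones((1, 1))
    else:
        # preferential-return flavour: transitions biased towards anchor 0 (home)
        weights = rng.uniform(0.5, 1.5, size=(n_anchors, n_anchors))
        weights[:, 0] *= 3.0
        np.fill_diagonal(weights, 0.0)  # a transition always changes anchor
        P = weights / weights.sum(axis=1, keepdims=True)
    dwell = rng.uniform(1.0, 4.0, size=n_anchors) * HOUR_S
    dwell[0] = 8.0 * HOUR_S
    cfg = dict(
        n_anchors=n_anchors,
        anchor_coords=np.array(coords),
        transition_matrix=P,
        dwell_mean_per_anchor=dwell,
        seed=seed,
    )
    cfg.update(overrides)
    return MobilityModelConfig(**cfg)


def generate_trajectory(
    config: MobilityModelConfig, user_id: str = "u0"
) -> tuple[Trajectory, GroundTruth]:
    """Simulate one user's trajectory and the true visit schedule behind it.

    Points are emitted on a fixed clock (every ``sampling_interval`` seconds
    from midnight) during dwells (anchor position + Gaussian noise) and along
    constant-speed straight travel legs; then whole hour-long windows are
    emptied at random until the hour-level missing fraction matches the
    target to within one window.  Identical configs give identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    horizon = config.duration_days * DAY_S
    ds = config.sampling_interval

    times: list[float] = []
    xs: list[float] = []
    ys: list[float] = []
    visits: list[tuple[int, float, float]] = []

    t = 0.0
    next_sample = 0.0
    anchor = 0
    while t < horizon:
        mean = config.dwell_mean_per_anchor[anchor]
        dwell = config.dwell_min + rng.exponential(max(mean - config.dwell_min, 1.0))
        dwell_end = min(t + dwell, horizon)
        ax, ay = config.anchor_coords[anchor]
        while next_sample < dwell_end:
            times.append(next_sample)
            xs.append(ax)
            ys.append(ay)
            next_sample += ds
        # merge consecutive visits to the same anchor
        if visits and visits[-1][0] == anchor and visits[-1][2] >= t:
            visits[-1] = (anchor, visits[-1][1], dwell_end)
        else:
            visits.append((anchor, t, dwell_end))
        if dwell_end >= horizon:
            break
        if config.n_anchors == 1:
            t = dwell_end
            continue
        nxt = int(rng.choice(config.n_anchors, p=config.transition_matrix[anchor]))
        bx, by = config.anchor_coords[nxt]
        dist = float(np.hypot(bx - ax, by - ay))
        travel = dist / config.travel_speed
        travel_end = min(dwell_end + travel, horizon)
        while next_sample < travel_end:
            frac = (next_sample - dwell_end) / travel if travel > 0 else 1.0
            times.append(next_sample)
            xs.append(ax + frac * (bx - ax))
            ys.append(ay + frac * (by - ay))
            next_sample += ds
        t = dwell_end + travel
        anchor = nxt

    times_a = np.asarray(times)
    xy = np.column_stack([xs, ys])
    if config.gnss_noise_sigma > 0:
        xy = xy + rng.normal(0.0, config.gnss_noise_sigma, size=xy.shape)

    keep = np.ones(len(times_a), dtype=bool)
    if config.missing_fraction_target > 0:
        n_hours = int(config.duration_days * 24)
        k = int(round(config.missing_fraction_target * n_hours))
        missing_hours = rng.choice(n_hours, size=k, replace=False)
        keep = ~np.isin(np.floor(times_a / HOUR_S).astype(np.int64), missing_hours)

    traj = Trajectory(
        user_id=user_id,
        x=xy[keep, 0],
        y=xy[keep, 1],
        t=from_epoch_seconds(T0_EPOCH_S + times_a[keep]),
    )
    truth = GroundTruth(
        true_visit_sequence=[
            (a, from_epoch_seconds(T0_EPOCH_S + s), from_epoch_seconds(T0_EPOCH_S + e))
            for a, s, e in visits
        ],
        anchor_coords=config.anchor_coords.copy(),
    )
    return traj, truth


def generate_markov_sequence(
    transition_matrix, n: int, seed: int, start: int | None = None
) -> list[int]:
    """A length-``n`` realisation of a Markov chain over integer symbols.

    Without an explicit ``start`` the initial state is drawn from the unique
    stationary distribution, so the chain must be irreducible; with ``start``
    given (e.g. for chains with absorbing states) no such requirement holds.
    """
    P = check_row_stochastic(transition_matrix)
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    k = P.shape[0]
    if start is None:
        pi = stationary_distribution(P)  # raises if not unique
        state = int(rng.choice(k, p=pi))
    else:
        state = int(start)
    out = [state]
    # draw all uniforms up front, invert per-row CDFs
    u = rng.random(n - 1)
    cdf = np.cumsum(P, axis=1)
    for i in range(n - 1):
        state = int(np.searchsorted(cdf[state], u[i], side="right"))
        state = min(state, k - 1)
        out.append(state)
    return out


__all__ = [
    "MobilityModelConfig",
    "GroundTruth",
    "random_config",
    "generate_trajectory",
    "generate_markov_sequence",
    "stationary_distribution",
    "is_irreducible",
]
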