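"""End-to-end experiment harness: populations, spatial/temporal sweeps, summaries.

Drives the full pipeline — simulate (or load) trajectories, detect
stay-points, aggregate into stay-regions at each parameter of a sweep, build
symbolic sequences, and compute entropies, predictabilities and sequence
properties — then summarises every metric across users by median and
interquartile range (linear-interpolation quantiles).

Per-user seeds are derived deterministically from the global seed and the
user index, so results do not depend on execution order and two runs with
the same configuration are identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from ._util import quantile_summary
from .entropy import predictability_profile
from .fitting import ScalingFit, fit_relationship  # re-exported for sweeps
from .regions import dbscan_aggregate, grid_aggregate, region_geometry
from .sequences import (
    RegionVisitSequence,
    build_next_place_sequence,
    build_time_bin_sequence,
    compute_q,
    sequence_stats,
    visits_from_assignment,
)
from .staypoints import StayPointSequence, detect_staypoints
from .synthetic import generate_trajectory, random_config

__all__ = [
    "PopulationConfig",
    "User",
    "SweepResult",
    "build_population",
    "run_spatial_sweep",
    "run_temporal_sweep",
    "summarize_distribution",
    "fit_relationship",
    "ScalingFit",
]

METRICS = [
    "pi_rand",
    "pi_unc",
    "pi_max",
    "n_records",
    "n_regions",
    "n_self_transitions",
    "q",
    "median_region_area",
    "single_point_fraction",
]


@dataclass
class PopulationConfig:
    """Settings of the default synthetic study population."""

    n_users: int = 50
    duration_days: int = 28
    n_anchors_min: int = 5
    n_anchors_max: int = 8
    extent: float = 8000.0
    sampling_interval: float = 60.0
    gnss_noise_sigma: float = 10.0
    missing_fraction_target: float = 0.04
    travel_speed: float = 10.0
    delta: float = 300.0  # stay-point distance threshold
    tau: float = 600.0  # stay-point minimum dwell, seconds
    seed: int = 0

    def validate(self) -> None:
        if self.n_users < 1 or self.duration_days < 1:
            raise ValueError("n_users and duration_days must be >= 1")
        if not self.n_anchors_min <= self.n_anchors_max:
            raise ValueError("n_anchors_min must be <= n_anchors_max")


@dataclass
class User:
    user_id: str
    trajectory: object
    ground_truth: object
    staypoints: StayPointSequence


@dataclass
class SweepResult:
    axis: Literal["spatial_grid", "spatial_dbscan", "temporal"]
    parameters: np.ndarray
    per_user: pd.DataFrame  # one row per (parameter, user)
    summary: pd.DataFrame = field(default=None)  # median/IQR per (parameter, metric)

    def __post_init__(self) -> None:
        if self.summary is None:
            rows = []
            for param, grp in self.per_user.groupby("parameter"):
                for metric in METRICS:
                    if metric not in grp:
                        continue
                    med, iqr = summarize_distribution(grp[metric].dropna())
                    rows.append(
                        {"parameter": param, "metric": metric, "median": med, "iqr": iqr}
                    )
            self.summary = pd.DataFrame(rows)


def summarize_distribution(values) -> tuple[float, float]:
    """(median, interquartile range), linear-interpolation quantiles."""
    return quantile_summary(values)


def build_population(config: PopulationConfig) -> list[User]:
    """Simulate the population and pre-compute each user's stay-points."""
    config.validate()
    users = []
    rng = np.random.default_rng(config.seed)
    anchor_counts = rng.integers(
        config.n_anchors_min, config.n_anchors_max + 1, size=config.n_users
    )
    for i in range(config.n_users):
        user_seed = int(
            np.random.SeedSequence([config.seed, i]).generate_state(1)[0] % 2**31
        )
        cfg = random_config(
            seed=user_seed,
            n_anchors=int(anchor_counts[i]),
            extent=config.extent,
            duration_days=config.duration_days,
            sampling_interval=config.sampling_interval,
            gnss_noise_sigma=config.gnss_noise_sigma,
            missing_fraction_target=config.missing_fraction_target,
            travel_speed=config.travel_speed,
        )
        uid = f"u{i:03d}"
        traj, truth = generate_trajectory(cfg, user_id=uid)
        sps = detect_staypoints(traj, delta=config.delta, tau=config.tau)
        users.append(User(uid, traj, truth, sps))
    return users


def _aggregate(staypoints: StayPointSequence, method: str, parameter: float):
    if method == "grid":
        return grid_aggregate(staypoints, parameter)
    if method == "dbscan":
        return dbscan_aggregate(staypoints, parameter)
    raise ValueError(f"unknown aggregation method {method!r}")


def _user_metrics(
    visits: RegionVisitSequence,
    sequence_type: str,
    delta_t: float | None,
) -> dict:
    if sequence_type == "time_bin":
        seq = build_time_bin_sequence(visits, delta_t)
        q = compute_q(seq)
    elif sequence_type == "next_place":
        seq = build_next_place_sequence(visits)
        q = 0.0
    else:
        raise ValueError(f"unknown sequence_type {sequence_type!r}")
    n_records, n_regions, n_self = sequence_stats(seq)
    row = {
        "n_records": n_records,
        "n_regions": n_regions,
        "n_self_transitions": n_self,
        "q": q,
        "flagged_short": False,
    }
    non_null = [s for s in seq.symbols if s is not None]
    if len(non_null) < 2 or len(set(non_null)) < 2:
        # a sequence collapsed to a single symbol is completely predictable
        row.update(pi_rand=1.0, pi_unc=1.0, pi_max=1.0, flagged_short=True)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            _, pred = predictability_profile(seq)
        row.update(pi_rand=pred.pi_rand, pi_unc=pred.pi_unc, pi_max=pred.pi_max)
    return row


def _sweep(
    population: list[User],
    axis: str,
    method: str,
    spatial_params,
    delta_t_values,
    sequence_type: str,
) -> SweepResult:
    rows = []
    combos = (
        [(p, delta_t_values[0] if delta_t_values else None) for p in spatial_params]
        if axis != "temporal"
        else [(spatial_params[0], dt) for dt in delta_t_values]
    )
    for param, dt in combos:
        for user in population:
            if len(user.staypoints) == 0:
                continue
            assignment = _aggregate(user.staypoints, method, param)
            geoms = region_geometry(user.staypoints, assignment)
            visits = visits_from_assignment(user.staypoints, assignment)
            row = _user_metrics(visits, sequence_type, dt)
            areas = [g.area for g in geoms]
            row.update(
                parameter=param if axis != "temporal" else dt,
                user_id=user.user_id,
                median_region_area=float(np.median(areas)),
                single_point_fraction=float(
                    np.mean([g.is_single_point for g in geoms])
                ),
            )
            rows.append(row)
    params = (
        np.asarray(spatial_params, dtype=float)
        if axis != "temporal"
        else np.asarray(delta_t_values, dtype=float)
    )
    return SweepResult(axis=axis, parameters=params, per_user=pd.DataFrame(rows))


def run_spatial_sweep(
    population: list[User],
    method: Literal["grid", "dbscan"],
    params,
    sequence_type: Literal["time_bin", "next_place"] = "time_bin",
    delta_t: float = 3600.0,
) -> SweepResult:
    """Sweep the spatial aggregation parameter at a fixed temporal resolution.

    For each parameter every user's stay-points are aggregated, turned into
    the requested sequence type, and profiled; users whose sequence collapses
    below two symbols are kept with all predictabilities 1 and flagged.
    """
    return _sweep(
        population,
        axis=f"spatial_{method}",
        method=method,
        spatial_params=list(params),
        delta_t_values=[delta_t],
        sequence_type=sequence_type,
    )


def run_temporal_sweep(
    population: list[User],
    delta_t_values,
    method: Literal["grid", "dbscan"] = "dbscan",
    spatial_param: float = 100.0,
) -> SweepResult:
    """Sweep the time-bin width at a fixed spatial aggregation (next time-bin
    sequences only; next place sequences have no temporal dimension)."""
    return _sweep(
        population,
        axis="temporal",
        method=method,
        spatial_params=[spatial_param],
        delta_t_values=list(delta_t_values),
        sequence_type="time_bin",
    )
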