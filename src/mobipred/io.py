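"""Text-format I/O for trajectories, stay-points, assignments and sequences.

All formats are plain delimiter-separated text with ISO-8601 UTC timestamps:

* trajectories      ``user_id,x,y,timestamp``
* stay-points       ``user_id,x,y,start,end``
* region assignment ``user_id,staypoint_index,region_id,region_x,region_y``
* time-bin sequence ``user_id,bin_start,region_id`` (empty region for null)
* place sequence    ``user_id,rank,region_id``

Coordinates are planar metres.  Lon/lat input is converted with a local
equirectangular projection (exact enough at city scale, the extent these
analyses target): x = R cos(lat0) dlon, y = R dlat about the data centroid.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .regions import RegionAssignment
from .sequences import PlaceSequence, TimeBinSequence
from .staypoints import StayPoint, StayPointSequence, Trajectory
from .synthetic import GroundTruth

EARTH_RADIUS_M = 6_371_008.8


def lonlat_to_metres(
    lon, lat, origin: tuple[float, float] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Project lon/lat (degrees) to planar metres about ``origin`` (lon0, lat0)."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    lon0, lat0 = origin if origin is not None else (lon.mean(), lat.mean())
    x = EARTH_RADIUS_M * math.cos(math.radians(lat0)) * np.radians(lon - lon0)
    y = EARTH_RADIUS_M * np.radians(lat - lat0)
    return x, y


def write_trajectory(traj: Trajectory, path) -> None:
    pd.DataFrame(
        {
            "user_id": traj.user_id,
            "x": traj.x,
            "y": traj.y,
            "timestamp": pd.to_datetime(traj.t).strftime("%Y-%m-%dT%H:%M:%SZ"),
        }
    ).to_csv(path, index=False)


def read_trajectories(path, lonlat: bool = False) -> dict[str, Trajectory]:
    """Read one or many users from a trajectory file, sorted by time."""
    df = pd.read_csv(path)
    required = {"user_id", "x", "y", "timestamp"}
    if not required.issubset(df.columns):
        raise ValueError(f"trajectory file must have columns {sorted(required)}")
    if lonlat:
        df["x"], df["y"] = lonlat_to_metres(df["x"], df["y"])
    out = {}
    for uid, grp in df.groupby("user_id", sort=True):
        grp = grp.sort_values("timestamp")
        out[str(uid)] = Trajectory(
            user_id=str(uid),
            x=grp["x"].to_numpy(),
            y=grp["y"].to_numpy(),
            t=pd.to_datetime(grp["timestamp"], utc=True)
            .dt.tz_localize(None)
            .to_numpy(),
        )
    return out


def write_staypoints(seqs: list[StayPointSequence], path) -> None:
    rows = [
        {
            "user_id": s.user_id,
            "x": sp.x,
            "y": sp.y,
            "start": pd.Timestamp(sp.start).strftime("%Y-%m-%dT%H:%M:%SZ"),
            "end": pd.Timestamp(sp.end).strftime("%Y-%m-%dT%H:%M:%SZ"),
        }
        for s in seqs
        for sp in s
    ]
    pd.DataFrame(rows, columns=["user_id", "x", "y", "start", "end"]).to_csv(
        path, index=False
    )


def read_staypoints(path, delta: float = 300.0, tau: float = 600.0) -> dict[str, StayPointSequence]:
    df = pd.read_csv(path)
    out: dict[str, StayPointSequence] = {}
    for uid, grp in df.groupby("user_id", sort=True):
        grp = grp.sort_values("start")
        sps = [
            StayPoint(
                x=float(r.x),
                y=float(r.y),
                start=np.datetime64(pd.Timestamp(r.start).tz_localize(None), "s"),
                end=np.datetime64(pd.Timestamp(r.end).tz_localize(None), "s"),
                n_member_points=int(getattr(r, "n_member_points", 1)),
            )
            for r in grp.itertuples()
        ]
        out[str(uid)] = StayPointSequence(str(uid), sps, delta=delta, tau=tau)
    return out


def write_assignment(user_id: str, assignment: RegionAssignment, path) -> None:
    rows = [
        {
            "user_id": user_id,
            "staypoint_index": i,
            "region_id": int(lab),
            "region_x": assignment.region_centres[int(lab)][0],
            "region_y": assignment.region_centres[int(lab)][1],
        }
        for i, lab in enumerate(assignment.labels)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_time_bin_sequence(seq: TimeBinSequence, path) -> None:
    rows = [
        {
            "user_id": seq.user_id,
            "bin_start": pd.Timestamp(seq.bin_start(k)).strftime("%Y-%m-%dT%H:%M:%SZ"),
            "region_id": "" if sym is None else int(sym),
        }
        for k, sym in enumerate(seq.symbols)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_place_sequence(seq: PlaceSequence, path) -> None:
    rows = [
        {"user_id": seq.user_id, "rank": k, "region_id": int(sym)}
        for k, sym in enumerate(seq.symbols)
    ]
    pd.DataFrame(rows, columns=["user_id", "rank", "region_id"]).to_csv(path, index=False)


def write_ground_truth(truth: GroundTruth, path) -> None:
    payload = {
        "anchor_coords": np.asarray(truth.anchor_coords).tolist(),
        "visits": [
            {
                "anchor": int(a),
                "start": str(np.datetime_as_string(np.datetime64(s, "s"))) + "Z",
                "end": str(np.datetime_as_string(np.datetime64(e, "s"))) + "Z",
            }
            for a, s, e in truth.true_visit_sequence
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))
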