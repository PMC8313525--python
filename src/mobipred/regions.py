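"""Spatial aggregation of stay-points into stay-regions.

Two aggregation families are supported: a regular grid tessellation (cell
size ``G``) and density clustering (DBSCAN with minimum cluster size one and
radius ``eps``).  With a minimum cluster size of one, DBSCAN reduces exactly
to the connected components of the graph that links stay-points at mutual
distance < eps, which is how it is implemented here (via a k-d tree); there
is no noise label, every stay-point belongs to a region.

Both methods illustrate the modifiable areal unit problem: the same dwell
history yields different symbol alphabets depending on the tessellation and
its scale, which propagates into entropy and predictability downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from shapely import MultiPoint

from .staypoints import StayPointSequence


@dataclass
class RegionAssignment:
    """Mapping of stay-points to dense integer region labels with centres."""

    method: str  # "grid" or "dbscan"
    parameter: float  # grid spacing G or DBSCAN radius eps, metres
    labels: np.ndarray  # one region id per stay-point
    region_centres: dict[int, tuple[float, float]]

    @property
    def n_regions(self) -> int:
        return len(self.region_centres)


@dataclass(frozen=True)
class StayRegionGeometry:
    region_id: int
    n_staypoints: int
    area: float  # convex-hull area of member stay-points, m^2
    is_single_point: bool


def _coords(staypoints) -> np.ndarray:
    if isinstance(staypoints, StayPointSequence):
        return staypoints.coords()
    arr = np.asarray(
        [[s.x, s.y] if hasattr(s, "x") else s for s in staypoints], dtype=float
    )
    return arr.reshape(-1, 2)


def _densify(raw_labels: np.ndarray) -> np.ndarray:
    """Relabel to dense 0..k-1 ids in order of first appearance."""
    seen: dict[int, int] = {}
    out = np.empty(len(raw_labels), dtype=int)
    for i, lab in enumerate(raw_labels):
        out[i] = seen.setdefault(int(lab), len(seen))
    return out


def grid_aggregate(staypoints, G: float, origin: tuple[float, float] | None = None) -> RegionAssignment:
    """Assign stay-points to cells of a regular axis-aligned grid.

    The grid is anchored at ``origin`` (default: the minimum corner of the
    stay-point bounding box) with half-open cells [x0+kG, x0+(k+1)G); each
    region's centre is its cell centre.
    """
    pts = _coords(staypoints)
    if G <= 0:
        raise ValueError("grid spacing G must be > 0")
    if len(pts) == 0:
        raise ValueError("need at least one stay-point")
    x0, y0 = origin if origin is not None else (pts[:, 0].min(), pts[:, 1].min())
    kx = np.floor((pts[:, 0] - x0) / G).astype(np.int64)
    ky = np.floor((pts[:, 1] - y0) / G).astype(np.int64)
    seen: dict[tuple[int, int], int] = {}
    labels = np.empty(len(pts), dtype=int)
    for i, cell in enumerate(zip(kx.tolist(), ky.tolist())):
        labels[i] = seen.setdefault(cell, len(seen))
    centres: dict[int, tuple[float, float]] = {}
    for i, lab in enumerate(labels):
        if lab not in centres:
            centres[int(lab)] = (
                float(x0 + (kx[i] + 0.5) * G),
                float(y0 + (ky[i] + 0.5) * G),
            )
    return RegionAssignment("grid", float(G), labels, centres)


def dbscan_aggregate(staypoints, eps: float) -> RegionAssignment:
    """Cluster stay-points with DBSCAN, minimum cluster size one.

    Equivalent to connected components of the graph linking points at
    distance strictly below ``eps``; region centres are member centroids.
    """
    pts = _coords(staypoints)
    if eps <= 0:
        raise ValueError("eps must be > 0")
    if len(pts) == 0:
        raise ValueError("need at least one stay-point")
    n = len(pts)
    tree = cKDTree(pts)
    pairs = tree.query_pairs(r=eps, output_type="ndarray")
    if len(pairs):
        d = np.hypot(*(pts[pairs[:, 0]] - pts[pairs[:, 1]]).T)
        pairs = pairs[d < eps]  # strict inequality
    rows = pairs[:, 0] if len(pairs) else np.empty(0, dtype=int)
    cols = pairs[:, 1] if len(pairs) else np.empty(0, dtype=int)
    graph = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    _, comp = connected_components(graph, directed=False)
    labels = _densify(comp)
    centres = {
        int(lab): tuple(pts[labels == lab].mean(axis=0)) for lab in np.unique(labels)
    }
    return RegionAssignment("dbscan", float(eps), labels, centres)


def region_geometry(staypoints, assignment: RegionAssignment) -> list[StayRegionGeometry]:
    """Per-region member count, convex-hull area and single-point flag."""
    pts = _coords(staypoints)
    if len(pts) != len(assignment.labels):
        raise ValueError("assignment does not match the stay-points")
    out = []
    for lab in sorted(assignment.region_centres):
        members = pts[assignment.labels == lab]
        # degenerate hulls (points, segments) have zero area
        area = float(MultiPoint(members).convex_hull.area) if len(members) >= 3 else 0.0
        out.append(
            StayRegionGeometry(
                region_id=int(lab),
                n_staypoints=len(members),
                area=area,
                is_single_point=len(members) == 1,
            )
        )
    return out


def parameter_sweep_values(n: int = 30, lo_exp: float = 1.0, hi_exp: float = 4.8) -> np.ndarray:
    """``n`` aggregation parameters log-uniform between 10**lo_exp and 10**hi_exp."""
    if n < 2:
        raise ValueError("need at least 2 sweep values")
    return np.logspace(lo_exp, hi_exp, n)
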