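"""Arc-length resampling, length/curvature measures and centroid-fiber extraction.

Every downstream shape comparison operates on :class:`PointCloud` objects:
fixed-size, arc-length-uniformly resampled polylines in world millimetres.
A bundle of many streamlines is reduced to a single representative fiber
(its *centroid*), implemented here as the medoid under the flip-invariant
pairwise distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from tractoshape.io_streamlines import BundleSet


@dataclass(frozen=True)
class PointCloud:
    """A fixed-size ordered 3-D point set representing one fiber centroid.

    Parameters
    ----------
    points:
        ``(n_points, 3)`` float array, millimetres, world (RAS) space.
        Points are ordered along the fiber; spacing is arc-length uniform
        when produced by :func:`resample_polyline`.
    source_id:
        Name of the originating bundle.
    """

    points: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"points must be (n, 3), got shape {pts.shape}")
        if pts.shape[0] < 2:
            raise ValueError("a point cloud needs at least 2 points")
        if not np.all(np.isfinite(pts)):
            raise ValueError("point cloud contains non-finite coordinates")
        object.__setattr__(self, "points", pts)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def reversed(self) -> "PointCloud":
        """The same curve traversed end-to-start (fibers have no orientation)."""
        return PointCloud(self.points[::-1].copy(), source_id=self.source_id)


def arc_length(points: np.ndarray | PointCloud) -> float:
    """Polyline arc length: sum of consecutive Euclidean gaps, in mm."""
    pts = points.points if isinstance(points, PointCloud) else np.asarray(points, dtype=float)
    if pts.shape[0] < 2:
        raise ValueError("arc length needs at least 2 points")
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def resample_polyline(
    streamline: np.ndarray | Sequence[Sequence[float]],
    n_points: int,
    source_id: str = "",
) -> PointCloud:
    """Resample a polyline at uniform arc-length fractions ``i/(n_points-1)``.

    Output points lie exactly on the piecewise-linear input curve; the first
    and last points coincide with the input endpoints. Linear interpolation,
    no smoothing.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    pts = np.asarray(streamline, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"streamline must be (n, 3), got {pts.shape}")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    total = seg.sum()
    if total <= 0.0:
        raise ValueError("cannot resample a zero-length streamline")
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, total, n_points)
    out = np.column_stack([np.interp(targets, cum, pts[:, k]) for k in range(3)])
    # endpoints exactly, immune to interp rounding
    out[0] = pts[0]
    out[-1] = pts[-1]
    return PointCloud(out, source_id=source_id)


def discrete_curvature(cloud: PointCloud | np.ndarray) -> tuple[float, float]:
    """Total turning angle (rad) and per-length curvature (rad/mm) of a polyline.

    The total turning is the sum of angles between consecutive segment
    directions; it is 0 for collinear clouds, ~pi for a semicircular arc,
    and invariant to rigid motions and uniform scaling (per-length curvature
    scales as 1/scale).
    """
    pts = cloud.points if isinstance(cloud, PointCloud) else np.asarray(cloud, dtype=float)
    if pts.shape[0] < 3:
        raise ValueError("curvature needs at least 3 points")
    d = np.diff(pts, axis=0)
    norms = np.linalg.norm(d, axis=1)
    if np.any(norms == 0):
        raise ValueError("degenerate zero-length segment")
    u = d / norms[:, None]
    cosang = np.clip(np.einsum("ij,ij->i", u[:-1], u[1:]), -1.0, 1.0)
    total = float(np.arccos(cosang).sum())
    return total, total / arc_length(pts)


def extract_centroid(bundle: "BundleSet", n_points: int) -> PointCloud:
    """Representative fiber of a bundle: the medoid after resampling.

    Every streamline is resampled to ``n_points``; the member minimizing the
    summed flip-invariant distance to all other members is returned. Ties
    are broken by lowest streamline index. A single-streamline bundle
    returns that streamline resampled.
    """
    from tractoshape.shape_distance import distance_matrix

    if len(bundle.streamlines) == 0:
        raise ValueError(f"bundle {bundle.name!r} has no streamlines")
    clouds = [
        resample_polyline(s, n_points, source_id=bundle.name) for s in bundle.streamlines
    ]
    if len(clouds) == 1:
        return clouds[0]
    dmat = distance_matrix(clouds).values
    sums = dmat.sum(axis=1)
    best = int(np.argmin(sums))  # argmin returns the first (lowest-index) minimiser
    return clouds[best]
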