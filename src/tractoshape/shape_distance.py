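"""Flip-invariant point-to-point distance between centroid fibers.

Two fibers represented by the same number of control points are compared
point-for-point in 3-D; because a fiber has no intrinsic start or end, the
distance is the minimum over the direct and the order-reversed pairing:

    d(c1, c2) = min( sqrt(sum_i |P1(i) - P2(i)|^2),
                     sqrt(sum_i |P1(i) - P2(Np-1-i)|^2) )

This is a quotient metric under the order-reversal isometry: symmetric,
non-negative, zero exactly when the clouds coincide up to reversal, and
satisfying the triangle inequality. Clouds are expected to be in a common
pose (see :mod:`tractoshape.alignment`); no per-pair re-alignment happens
inside the distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from tractoshape.geometry import PointCloud


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric N x N matrix of flip-invariant distances (mm) with cloud ids."""

    values: np.ndarray
    ids: tuple[str, ...]

    def __post_init__(self) -> None:
        V = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if V.shape != (n, n):
            raise ValueError(f"values shape {V.shape} does not match {n} ids")
        if not np.all(np.isfinite(V)):
            raise ValueError("distance matrix contains non-finite entries")
        if np.any(V < 0):
            raise ValueError("distance matrix contains negative entries")
        if not np.allclose(V, V.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(V), 0.0):
            raise ValueError("distance matrix diagonal is not zero")
        object.__setattr__(self, "values", V)
        object.__setattr__(self, "ids", tuple(self.ids))

    @property
    def n(self) -> int:
        return len(self.ids)


def _check_same_np(clouds: Sequence[PointCloud]) -> int:
    counts = {c.n_points for c in clouds}
    if len(counts) > 1:
        offenders = [
            f"{c.source_id or i}:{c.n_points}" for i, c in enumerate(clouds)
        ]
        raise ValueError("mixed point counts: " + ", ".join(offenders))
    return counts.pop()


def pairwise_distance(c1: PointCloud, c2: PointCloud) -> float:
    """Flip-invariant distance (mm) between two equally sized clouds."""
    if c1.n_points != c2.n_points:
        raise ValueError(f"point count mismatch: {c1.n_points} vs {c2.n_points}")
    diff_fwd = c1.points - c2.points
    diff_rev = c1.points - c2.points[::-1]
    return float(
        min(
            np.sqrt(np.sum(diff_fwd**2)),
            np.sqrt(np.sum(diff_rev**2)),
        )
    )


def distance_matrix(clouds: Sequence[PointCloud]) -> DistanceMatrix:
    """All pairwise flip-invariant distances, computed once per unordered pair.

    Vectorized: each cloud is flattened to a 3*Np vector, so the direct and
    reversed sums become two Euclidean distance matrices whose entrywise
    minimum is taken.
    """
    if len(clouds) == 0:
        raise ValueError("need at least one cloud")
    _check_same_np(clouds)
    ids = tuple(c.source_id or f"cloud{i}" for i, c in enumerate(clouds))
    X = np.stack([c.points.ravel() for c in clouds])
    X_rev = np.stack([c.points[::-1].ravel() for c in clouds])
    D = np.minimum(cdist(X, X), cdist(X, X_rev))
    D = np.minimum(D, D.T)  # exact symmetry despite floating-point order
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(D, ids)
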