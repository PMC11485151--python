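"""Pose normalization and cloud-to-cloud registration.

Two alignment operations are provided:

* :func:`pca_align` puts every cloud in a deterministic canonical pose
  (principal axes mapped to x/y/z in decreasing-variance order, signs fixed
  by a third-moment rule) so that all pairwise distances are computed in a
  single common frame.
* :func:`align_to_reference` rigidly registers one cloud onto a reference
  (Kabsch / orthogonal Procrustes restricted to proper rotations),
  optionally also trying the reversed point order, and reports the RMSD.

Alignment is rigid only — rotation plus translation, no scaling or shear —
because absolute fiber length carries a biological signal (species
differences in bundle length) that scaling would erase.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from tractoshape.geometry import PointCloud

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class RigidTransform:
    """A rigid (or, for pose canonicalization, orthogonal) map x -> R x + t.

    ``rotation`` is orthogonal within 1e-9. ``det(rotation)`` is +1 for
    physical rigid motions; pca_align may return det = -1 when its sign
    convention requires an axis reflection to reach the canonical pose.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R @ R.T, np.eye(3), atol=_ORTHO_TOL * 10):
            raise ValueError("rotation matrix is not orthogonal")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(Rinv, -Rinv @ self.translation)

    @property
    def is_reflection(self) -> bool:
        return bool(np.linalg.det(self.rotation) < 0)


def _sign_fix(projected: np.ndarray, axes: np.ndarray) -> np.ndarray:
    """Resolve the sign ambiguity of each principal axis deterministically.

    Primary statistic: the ends-vs-middle contrast, i.e. the covariance of
    the coordinate with the reversal-symmetric index weight
    ``(i - (n-1)/2)^2``. Because the weight is symmetric under point-order
    reversal, the canonical pose does not depend on the stored traversal
    direction (that ambiguity is absorbed by the flip term of the pairwise
    distance), and the statistic stays well away from zero for curves whose
    middle and extremities sit at different coordinates — where the third
    central moment of an arc-length-uniform curve is often near zero and
    noise-fragile. Fallbacks: third central moment, then the first point's
    coordinate.
    """
    n = projected.shape[0]
    w = (np.arange(n) - (n - 1) / 2.0) ** 2
    w = w - w.mean()
    w_scale = np.sqrt(np.mean(w**2))
    scale = np.sqrt(np.mean(projected**2, axis=0)) + 1e-300
    for j in range(3):
        x = projected[:, j]
        contrast = float(np.mean(w * x))
        tol_c = 1e-9 * w_scale * scale[j]
        m3 = float(np.mean(x**3))
        tol_m = 1e-9 * scale[j] ** 3
        if abs(contrast) > tol_c:
            flip = contrast < 0
        elif abs(m3) > tol_m:
            flip = m3 < 0
        else:
            flip = x[0] < 0
        if flip:
            projected[:, j] *= -1.0
            axes[:, j] *= -1.0
    return axes


def pca_align(cloud: PointCloud) -> tuple[PointCloud, RigidTransform]:
    """Map a cloud to its canonical PCA pose.

    The output is centered at the origin with principal axes of decreasing
    variance along x, y, z. The inherent sign ambiguity of eigenvectors is
    resolved by requiring a non-negative third central moment along each
    axis (falling back to a non-negative first-point coordinate for
    symmetric distributions). The convention is deterministic and covariant
    under rigid motions of the input, so canonical poses of rigidly moved
    copies coincide.

    Rank-deficient clouds (collinear or planar) are aligned within their
    span; the remaining axes follow the same sign rule and a warning is
    emitted. All points coincident is an error.
    """
    pts = cloud.points
    center = pts.mean(axis=0)
    X = pts - center
    cov = X.T @ X / X.shape[0]
    evals, evecs = np.linalg.eigh(cov)  # ascending
    order = np.argsort(evals, kind="stable")[::-1]
    evals = evals[order]
    axes = evecs[:, order]
    if evals[0] <= 1e-24:
        raise ValueError("all points coincident: no principal axes")
    if evals[2] <= 1e-12 * evals[0]:
        warnings.warn(
            f"cloud {cloud.source_id!r} is rank-deficient; aligned within its span",
            stacklevel=2,
        )
    Y = X @ axes
    axes = _sign_fix(Y, axes)
    R = axes.T
    transform = RigidTransform(R, -R @ center)
    return PointCloud(Y, source_id=cloud.source_id), transform


def _kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Proper rotation R and translation t minimizing ||R P + t - Q||."""
    p0 = P.mean(axis=0)
    q0 = Q.mean(axis=0)
    H = (P - p0).T @ (Q - q0)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = q0 - R @ p0
    return R, t


def align_to_reference(
    cloud: PointCloud,
    reference: PointCloud,
    allow_flip: bool = True,
) -> tuple[PointCloud, float, RigidTransform]:
    """Rigidly register ``cloud`` onto ``reference``; return (aligned, RMSD, T).

    Minimizes the root-mean-square point-to-point deviation over proper
    rotations and translations, and — when ``allow_flip`` — additionally
    over reversal of the point order of ``cloud`` (fibers carry no intrinsic
    orientation). The reported RMSD never exceeds the RMSD of the
    untransformed pair.
    """
    if cloud.n_points != reference.n_points:
        raise ValueError(
            f"point count mismatch: {cloud.n_points} vs {reference.n_points}"
        )
    Q = reference.points
    best: tuple[float, np.ndarray, RigidTransform] | None = None
    candidates = [cloud.points]
    if allow_flip:
        candidates.append(cloud.points[::-1])
    for P in candidates:
        R, t = _kabsch(P, Q)
        aligned = P @ R.T + t
        rmsd = float(np.sqrt(np.mean(np.sum((aligned - Q) ** 2, axis=1))))
        if best is None or rmsd < best[0]:
            best = (rmsd, aligned, RigidTransform(R, t))
    rmsd, aligned, transform = best
    return PointCloud(aligned, source_id=cloud.source_id), rmsd, transform
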