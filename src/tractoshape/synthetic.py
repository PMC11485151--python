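"""Parametric generator of the eight empirical fiber-bundle shape families.

Superficial white-matter bundles fall, on visual inspection, into eight
recurring silhouettes: straight (I), bent (L), narrow-aperture (V),
half-circle (U), shallower arc (Open-U), strongly enclosed arc (C), hooked
(J) and nearly-closed-with-a-tail (6). This module synthesizes centroid
point clouds for each family from simple piecewise arc/segment curves, with
per-point Gaussian jitter, light smoothing and a random rigid pose, so the
whole shape-analysis pipeline can be exercised and benchmarked without any
imaging data.

All canonical shapes have total arc length equal to ``scale`` (default
40 mm, a typical superficial-bundle length), which gives every family a
closed-form arc length, total turning angle and endpoint separation at zero
noise. Arc spans per family are declared conventions chosen to respect the
taxonomy's ordering of edge enclosure (Open-U < U < C < 6); all are
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from tractoshape.geometry import PointCloud

#: Family name -> default geometry parameters (fractions of ``scale`` where
#: lengths are concerned, radians where angles are concerned).
SHAPE_FAMILIES: dict[str, dict[str, float]] = {
    "I": {},
    "L": {"bend": np.pi / 2, "arm_fraction": 0.75},
    "V": {"aperture": np.pi / 5, "arm_fraction": 0.5},
    "U": {"span": np.pi},
    "OpenU": {"span": 2 * np.pi / 3},
    "C": {"span": 3 * np.pi / 2},
    "J": {"span": 3 * np.pi / 4, "arm_fraction": 0.5},
    "Six": {"span": 11 * np.pi / 6, "tail_fraction": 0.2},
}

#: Per-family sampling ranges used by :func:`generate_cohort`. Arc spans are
#: non-overlapping and ordered by edge enclosure (OpenU < U < C < Six), with
#: adjacent ranges touching so the cohort forms a shape continuum rather
#: than eight isolated islands — mirroring how real bundle shapes grade into
#: one another.
FAMILY_PARAM_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    "I": {},
    "L": {"bend": (5 * np.pi / 12, 7 * np.pi / 12), "arm_fraction": (0.7, 0.85)},
    "V": {"aperture": (np.pi / 3, np.pi / 2)},
    "OpenU": {"span": (np.pi / 2, 5 * np.pi / 6)},
    "U": {"span": (5 * np.pi / 6, 7 * np.pi / 6)},
    "C": {"span": (5 * np.pi / 4, 8 * np.pi / 5)},
    "J": {"span": (2 * np.pi / 3, 5 * np.pi / 6), "arm_fraction": (0.25, 0.45)},
    "Six": {"span": (8 * np.pi / 5, 12 * np.pi / 7), "tail_fraction": (0.2, 0.3)},
}

#: Relative bundle length per family, applied on top of the cohort ``scale``.
#: Empirically the flattest bundles (I, L) are the longest and the enclosed
#: ones the shortest; the generator amplifies that ordering so that at desk
#: scale the flat families form a geometrically distinct lobe of shape space
#: rather than blending into the gently curved arcs.
FAMILY_SCALE: dict[str, float] = {
    "I": 1.6,
    "L": 1.45,
    "V": 1.0,
    "OpenU": 1.0,
    "U": 1.0,
    "J": 1.0,
    "C": 1.15,
    "Six": 1.2,
}

FLAT_FAMILIES = ("I", "L")
CURVED_FAMILIES = ("V", "U", "OpenU", "C", "J", "Six")


def mixture_spec(flat_fraction: float, n: int) -> dict[str, int]:
    """Per-family counts for a group with the given fraction of flat bundles.

    Flat counts are split evenly between I and L, curved counts spread
    evenly over the six curved families (remainders to the earlier
    families); used to build e.g. a flat-heavy vs a curved-heavy group pair.
    """
    if not 0.0 <= flat_fraction <= 1.0:
        raise ValueError("flat_fraction must be in [0, 1]")
    n_flat = round(flat_fraction * n)
    counts: dict[str, int] = {}
    for i, fam in enumerate(FLAT_FAMILIES):
        counts[fam] = n_flat // len(FLAT_FAMILIES) + (1 if i < n_flat % len(FLAT_FAMILIES) else 0)
    n_curved = n - n_flat
    for i, fam in enumerate(CURVED_FAMILIES):
        counts[fam] = n_curved // len(CURVED_FAMILIES) + (1 if i < n_curved % len(CURVED_FAMILIES) else 0)
    return counts


def sample_family_params(family: str, rng: np.random.Generator) -> dict[str, float]:
    """Draw one cloud's family parameters uniformly from the family's ranges."""
    return {
        name: float(rng.uniform(lo, hi))
        for name, (lo, hi) in FAMILY_PARAM_RANGES[family].items()
    }


@dataclass(frozen=True)
class SyntheticCohort:
    """A generated set of labeled centroid clouds."""

    clouds: tuple[PointCloud, ...]
    family_of: dict[str, str]
    group_of: dict[str, str]
    seed: int
    noise_sigma: float

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(c.source_id for c in self.clouds)


def _arc(radius: float, span: float, t: np.ndarray) -> np.ndarray:
    """Arc from the origin with initial tangent +x, curving toward +y."""
    ang = span * t
    return np.column_stack(
        [radius * np.sin(ang), radius * (1.0 - np.cos(ang)), np.zeros_like(ang)]
    )


def _two_arm(scale: float, turn: float, arm_fraction: float, t: np.ndarray) -> np.ndarray:
    """Two straight arms joined at a corner where the direction turns by ``turn``."""
    corner_t = arm_fraction
    pts = np.zeros((t.size, 3))
    first = t <= corner_t
    pts[first, 0] = t[first] * scale
    corner = np.array([corner_t * scale, 0.0, 0.0])
    d = np.array([np.cos(turn), np.sin(turn), 0.0])
    rest = ~first
    pts[rest] = corner + (t[rest] - corner_t)[:, None] * scale * d
    return pts


def _family_points(
    family: str, scale: float, t: np.ndarray, params: Mapping[str, float]
) -> np.ndarray:
    """Evaluate the canonical curve of a family at arc-length fractions ``t``."""
    p = dict(SHAPE_FAMILIES[family], **params)
    if family == "I":
        return np.column_stack([t * scale, np.zeros_like(t), np.zeros_like(t)])
    if family == "L":
        return _two_arm(scale, p["bend"], p["arm_fraction"], t)
    if family == "V":
        # aperture = total deviation of the two arms from collinear, i.e. the
        # turn at the corner of a wide shallow V (empirically, V bundles are
        # long and gently opened, close to Open-U arcs)
        pts = _two_arm(scale, p["aperture"], p["arm_fraction"], t)
        fan = p.get("fan", 0.0)
        if fan > 0.0:
            # fanned extremities: the outer part of each arm flares away from
            # the corner, quadratically with distance along the arm
            corner_t = p["arm_fraction"]
            along = np.where(t <= corner_t, (corner_t - t) / corner_t,
                             (t - corner_t) / (1.0 - corner_t))
            side = np.where(t <= corner_t, -1.0, 1.0)
            pts[:, 1] += fan * scale * side * along**2
        return pts
    if family in ("U", "OpenU", "C"):
        span = p["span"]
        radius = p.get("radius", scale / span)
        return _arc(radius, span, t)
    if family == "J":
        arm = p["arm_fraction"]
        span = p["span"]
        radius = (1.0 - arm) * scale / span
        pts = np.zeros((t.size, 3))
        straight = t <= arm
        pts[straight, 0] = t[straight] * scale
        rest = ~straight
        hook = _arc(radius, span, (t[rest] - arm) / (1.0 - arm))
        pts[rest] = hook + np.array([arm * scale, 0.0, 0.0])
        return pts
    if family == "Six":
        tail = p["tail_fraction"]
        span = p["span"]
        radius = (1.0 - tail) * scale / span
        pts = np.zeros((t.size, 3))
        straight = t <= tail
        pts[straight, 0] = t[straight] * scale
        rest = ~straight
        loop = _arc(radius, span, (t[rest] - tail) / (1.0 - tail))
        pts[rest] = loop + np.array([tail * scale, 0.0, 0.0])
        return pts
    raise ValueError(f"unknown shape family {family!r}; known: {sorted(SHAPE_FAMILIES)}")


def expected_turning(family: str, n_points: int, **params: float) -> float:
    """Closed-form total turning of the *discretized* canonical curve.

    A circular arc of span ``s`` sampled at ``n`` uniform arc-length points
    has discrete turning ``s * (n - 2) / (n - 1)`` (the two endpoint chords
    contribute half a step each); straight pieces contribute 0 and corners
    their exterior angle.
    """
    p = dict(SHAPE_FAMILIES[family], **params)
    if family == "I":
        return 0.0
    if family == "L":
        return float(p["bend"])
    if family == "V":
        return float(p["aperture"])
    if family in ("U", "OpenU", "C"):
        s = p["span"]
        return float(s * (n_points - 2) / (n_points - 1))
    # piecewise families: compute from the exact discretization
    t = np.linspace(0.0, 1.0, n_points)
    pts = _family_points(family, 100.0, t, params)
    from tractoshape.geometry import discrete_curvature

    return discrete_curvature(pts)[0]


def random_rigid_pose(rng: np.random.Generator, translation_scale: float) -> tuple[np.ndarray, np.ndarray]:
    """Uniform random proper rotation (QR of a Gaussian matrix) + translation."""
    M = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(M)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1.0
    t = rng.uniform(-translation_scale, translation_scale, size=3)
    return Q, t


def generate_shape(
    family: str,
    scale: float = 40.0,
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
    n_points: int = 21,
    pose: bool = True,
    source_id: str = "",
    **params: float,
) -> PointCloud:
    """One synthetic centroid cloud of the given family.

    The canonical curve is sampled at ``n_points`` uniform arc-length
    fractions, iso-Gaussian jitter of sd ``noise_sigma`` (mm) is added per
    point, the jittered interior is smoothed with a window-3 moving average
    so the cloud stays curve-like, and finally a random rigid pose is
    applied (skipped when ``pose`` is false or no rng is supplied).
    """
    if scale <= 0:
        raise ValueError("scale must be > 0")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if family not in SHAPE_FAMILIES:
        raise ValueError(f"unknown shape family {family!r}; known: {sorted(SHAPE_FAMILIES)}")
    t = np.linspace(0.0, 1.0, n_points)
    pts = _family_points(family, scale, t, params)
    if noise_sigma > 0:
        if rng is None:
            raise ValueError("noise_sigma > 0 requires an rng")
        pts = pts + rng.normal(0.0, noise_sigma, size=pts.shape)
        smoothed = pts.copy()
        smoothed[1:-1] = (pts[:-2] + pts[1:-1] + pts[2:]) / 3.0
        pts = smoothed
    if pose:
        if rng is None:
            raise ValueError("pose=True requires an rng")
        Q, trans = random_rigid_pose(rng, translation_scale=2.0 * scale)
        pts = pts @ Q.T + trans
    return PointCloud(pts, source_id=source_id or family)


def generate_cohort(
    spec: Mapping[str, int] | Mapping[str, Mapping[str, int]],
    n_points: int = 21,
    noise_sigma: float = 1.2,
    scale: float = 40.0,
    seed: int = 0,
    scale_jitter: float = 0.15,
    vary_params: bool = True,
) -> SyntheticCohort:
    """Generate a labeled cohort with exact per-family counts.

    ``spec`` is either ``{family: count}`` (a single group tagged ``"all"``)
    or ``{group: {family: count}}`` for multi-group mixtures. Generation is
    deterministic under ``seed``: the same seed reproduces bit-identical
    coordinates. Default noise is 1.2 mm, i.e. 3% of the default 40 mm
    shape scale.

    Per-cloud shape parameters (arc span, bend, aperture) are sampled from
    the non-overlapping family ranges of :data:`FAMILY_PARAM_RANGES` and
    total length from ``scale * U(1 - scale_jitter, 1 + scale_jitter)``, so
    the cohort spans a realistic within-family variability; set
    ``vary_params=False`` and ``scale_jitter=0`` for identical canonical
    shapes per family.
    """
    if n_points < 4:
        raise ValueError("n_points must be >= 4 to resolve family curvature")
    if not spec:
        raise ValueError("empty cohort spec")
    nested = any(isinstance(v, Mapping) for v in spec.values())
    groups: Mapping[str, Mapping[str, int]]
    groups = spec if nested else {"all": spec}  # type: ignore[assignment]
    rng = np.random.default_rng(seed)
    clouds: list[PointCloud] = []
    family_of: dict[str, str] = {}
    group_of: dict[str, str] = {}
    total = 0
    for group in groups:
        for family, count in groups[group].items():
            if family not in SHAPE_FAMILIES:
                raise ValueError(f"unknown shape family {family!r}")
            if count < 0:
                raise ValueError("counts must be >= 0")
            for i in range(count):
                uid = f"{group}/{family}/{i:03d}"
                params = sample_family_params(family, rng) if vary_params else {}
                jitter = (
                    1.0 + rng.uniform(-scale_jitter, scale_jitter)
                    if scale_jitter > 0
                    else 1.0
                )
                cloud_scale = scale * FAMILY_SCALE[family] * jitter
                cloud = generate_shape(
                    family,
                    scale=cloud_scale,
                    # noise tracks the cloud's own size: 1.2 at scale 40 is 3%
                    noise_sigma=noise_sigma * cloud_scale / scale,
                    rng=rng,
                    n_points=n_points,
                    source_id=uid,
                    **params,
                )
                clouds.append(cloud)
                family_of[uid] = family
                group_of[uid] = group
                total += 1
    if total == 0:
        raise ValueError("cohort spec has no positive counts")
    return SyntheticCohort(
        clouds=tuple(clouds),
        family_of=family_of,
        group_of=group_of,
        seed=seed,
        noise_sigma=noise_sigma,
    )
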