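# Methods

## The model

A fiber bundle's morphology is summarized by a single *centroid fiber*: a
representative streamline resampled to `Np` points at uniform arc length.
We use the medoid — the member minimizing the summed flip-invariant
distance to all other members after resampling — because a medoid is an
anatomically realizable fiber, whereas a pointwise mean of unregistered
streamlines need not be. The choice is encapsulated in
`geometry.extract_centroid` and can be swapped.

`Np` defaults to 21. The value is a convention, not an estimate: it is
small enough that a 320-bundle analysis takes seconds and large enough to
resolve the hooks that distinguish C- and 6-shapes from U-shapes.
Resampling is linear interpolation along the polyline; no spline
smoothing (reproducibility over cosmetics). Note that arc-length-uniform
samples have uniform spacing *along the curve*; their chord spacing is
shorter wherever a corner falls between samples.

All analysis is done on clouds in a **common canonical pose** produced by
PCA: center at the origin, principal axes mapped to x ≥ y ≥ z variance
order. Alignment is rigid only — no scaling or shear — because absolute
length carries the biological signal analyzed downstream (species length
contrasts); per-pair registration inside the distance is deliberately
avoided, matching the pipeline order (pose first, then distances).

### Axis-sign convention

Eigenvectors are defined up to sign, and that ambiguity must be resolved
identically for every cloud or canonical poses of near-identical shapes
end up 180° apart. The third central moment — the textbook disambiguator —
is unusable here: for arc-length-uniform curves it is *exactly zero* along
the dominant axis of many of the taxonomy's shapes (a V's coordinate
distribution along its bisector is uniform; a symmetric U's likewise), so
under a few percent of positional noise its sign is a coin flip. We
instead orient each axis by the **ends-vs-middle contrast**: the
covariance of the coordinate with the reversal-symmetric index weight
`(i − (n−1)/2)²`. This statistic is large for exactly the shapes whose
skewness vanishes (ends and middle of a curve rarely share a coordinate),
is rotation-covariant, and — because the weight is symmetric under point
reversal — is independent of the stored traversal direction, leaving that
ambiguity entirely to the flip term of the distance. Fallbacks, in order:
third central moment, then the first point's coordinate. Shapes that are
nearly rotation-symmetric in a plane (arcs approaching a full circle)
remain intrinsically unstable under *any* axis convention; see
Limitations.

### Distance

The flip-invariant point-to-point distance between equally sized clouds is
the minimum of the direct and order-reversed pairings of the summed
squared 3-D point differences (square-rooted). It is a quotient metric
under the reversal isometry: symmetric, non-negative, zero exactly on
reversal-equivalent clouds, triangle inequality. The reversed index is
`Np−1−i` (a printed form `Np−i` would be out of range at i = 0 under
0-based indexing).

### Embedding and clustering

Isomap in its classical form: k-NN graph (union symmetrization, distance
ties broken toward the lower index for determinism), Dijkstra all-pairs
geodesics (`scipy.sparse.csgraph`), double-centered classical MDS, top
eigenpairs, coordinates scaled by the square root of the eigenvalues,
each axis's sign fixed so its largest-magnitude loading is positive.
`n_neighbors` defaults to 4, `n_dims` to 2; the residual variance
`1 − r²(geodesic, embedded)` is reported as the fit diagnostic.

Disconnected k-NN graphs have three explicit policies: `error` (library
default), `largest_component`, and `bridge`, which repeatedly inserts the
single shortest edge between two components. The pipeline defaults to
`bridge`: cohorts with well-separated shape families can island at small
neighbor counts, and downstream group statistics need every cloud
embedded. A bridged component's geodesics are stretched by its bridge
edge; the residual variance reflects this.

k-means (k-means++ initialization, best of `n_init = 10` restarts, fixed
seed) runs in the embedding. No automatic k selection: `sweep_k` reports
inertia and mean silhouette, and k is raised until clusters show
distinctly different average shapes (k = 2 gives the flat/curved split,
k ≈ 5 the finer families). Cluster average shapes take the member nearest
the cluster center in embedding coordinates as reference, rigidly align
every member to it (Kabsch, point-order flip allowed), and average
pointwise — the reference-as-member reading keeps the average anchored to
a realizable fiber pose.

### Morphometry

Length statistics are mean ± population (N-divisor) standard deviation of
centroid arc lengths per shape class. Cross-group comparison multiplies
the source group's lengths by `sqrt(S_target / S_source)` of the pial
surface areas (lengths scale with the linear size of the cortex); the
areas are explicit user inputs, never computed from meshes. The percent
difference uses the target group's mean as denominator, with positive
values meaning the normalized source bundles are longer.

## The synthetic generator

`synthetic` emulates the eight empirical shape families as piecewise
segment/arc curves in a canonical plane, sampled at `Np` uniform
arc-length fractions, jittered with iso-Gaussian noise per point, lightly
smoothed (window-3 moving average on interior points, so noisy clouds stay
curve-like), and placed in a random rigid pose. Conventions that matter:

- **Canonical parameters** (single-shape default): I straight; L bend π/2
  with arm fraction 0.75 (a letter L has a long arm and a short foot — an
  equal-armed right angle at fixed arc length has the footprint of half a
  square and is metrically nearer the arcs than to a straight bundle);
  V aperture π/5, read as the corner turn of a wide shallow V (empirically
  V bundles are long, gently opened and routinely merge with Open-U in
  clustering; a hairpin reading would contradict that); U arc span π;
  Open-U 2π/3; C 3π/2; J straight arm plus a 3π/4 hook; 6 an 11π/6 loop
  with a tangent-continuous tail.
- **Cohort sampling.** Families are ranges, not points: arc spans are
  drawn from non-overlapping, mostly touching ranges ordered by enclosure
  (Open-U π/2–5π/6, U 5π/6–7π/6, C 5π/4–8π/5, 6 8π/5–12π/7 with tail
  fraction 0.2–0.3), bends/apertures likewise, and total length gets ±15%
  jitter. Touching ranges make the cohort a shape *continuum*, which is
  what the k-NN graph of real atlases sees; identical copies per family
  would produce isolated cliques no embedding can relate. The 6-shape's
  tail is kept ≥ 0.2 of its length because the loop alone is nearly
  rotation-symmetric and its canonical pose would be noise-unstable.
- **Length–shape correlation.** Per-family length multipliers
  (I 1.6, L 1.45, C 1.15, 6 1.2, others 1.0 × the 40 mm base scale)
  reproduce, in amplified form, the empirical ordering in which the
  flattest bundles are the longest and the enclosed ones the shortest.
  The amplification is a deliberate study condition: at equal arc length
  the point-to-point metric sees mostly bundle extent, and a desk-scale
  cohort (40 clouds per family) needs the flat lobe of shape space to be
  a distinct mode for the taxonomy's primary flat/curved split to be the
  dominant axis of variability, as it is in the real atlases where family
  frequencies are far from uniform.
- **Noise** defaults to 1.2 mm — 3% of the 40 mm base scale — and scales
  with each cloud's own length.

What the generator does *not* emulate: sulcal anatomy, fanning extremity
geometry (a V "fan" flag exists but is off by default), within-bundle
streamline dispersion (cohorts are centroids directly), spatial
correlation of noise, and realistic family frequencies. Passing the
cohort benchmarks therefore demonstrates that the pipeline recovers
shape structure *when the taxonomy's geometry holds*, not that real
atlases satisfy it.

## Numerical choices

- Distance matrices are computed vectorized (two `cdist` calls on
  flattened clouds) and symmetrized by an entrywise min with the
  transpose to kill last-ulp asymmetry; diagonal forced to zero.
- Eigen-decompositions use `numpy.linalg.eigh` on symmetrized matrices;
  MDS eigenvalues below a relative 1e-9 tolerance of the leading one may
  be clipped to zero, and a negative eigenvalue beyond that tolerance in
  the requested dimensions raises rather than silently truncating.
- k-means cluster indices are relabeled by first appearance so a fixed
  seed yields a canonical labeling.
- The pipeline derives one seed per stochastic stage as
  `seed XOR crc32(stage_name) mod 2^31`; artifacts are written with fixed
  `%.17g` float formatting and sorted JSON keys, making runs
  byte-reproducible.
- Degenerate inputs: coincident points refuse to align; rank-deficient
  (collinear/planar) clouds align within their span with a warning;
  zero-length streamlines refuse to resample; empty bundles refuse a
  centroid; bundles emptied by the length filter are dropped and logged.

## Problem sizes

The default benchmark cohort is 8 families × 40 clouds (N = 320,
Np = 21), the two-group contrast 2 × 100 clouds over ten seeds, and the
oracle checks use 20–30 objects. These sizes keep the full suite and the
acceptance study in the seconds-to-a-minute range on one CPU while
leaving each family enough members for composition percentages to be
meaningful.

## Limitations

- The point-to-point metric on globally posed clouds conflates size with
  shape; two shapes of similar bounding box but different curvature can
  be closer than two sizes of the same shape. This mirrors the analyzed
  pipeline but means length normalization decisions materially affect
  clustering.
- Canonical poses of nearly rotation-symmetric shapes (arcs → full
  circles) are unstable under noise; the generator avoids that regime,
  real data may not.
- ICP refinement after PCA is available (`align_to_reference`) but not
  used per-pair inside the distance, by design.
- Pial surface areas are user-supplied constants; no mesh processing.
- V-shaped bundles are expected to merge with U/Open-U clusters rather
  than form their own; the benchmarks tolerate exactly that merging.
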