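# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `phytopoint`. All internal computation is in millimetres
in a z-up frame (gravity along −z); report layers convert to cm / cm² /
cm³ and degrees with half-away-from-zero rounding at one decimal, the
convention of printed field tables.

## Preprocessing

**Voxel filter.** One centroid per occupied cubic voxel, grid anchored
explicitly (default: the cloud's minimum corner). The anchor matters:
the completeness score compares voxel *counts* between two clouds, which
is only meaningful on a single shared grid, so `completeness_score`
anchors both filters at the reference cloud's minimum corner. Default
pitch 5 mm, the sensor-evaluation convention.

**Statistical outlier removal.** A point survives iff its mean distance
to its k nearest neighbours is at most the global mean plus
`std_ratio` × the global standard deviation of those per-point means.
Defaults k = 20, ratio = 2.0 — the common defaults for this filter
family; the exact parameters are application-specific and exposed. Note
that on any finite regular grid the boundary points have larger k-NN
means than interior points for k > 2, so "a grid loses nothing" only
holds when every point's neighbour set is metrically identical.

**Normal estimation.** Smallest eigenvector of the covariance of the
radius neighbourhood (≥ 3 neighbours required; isolated points get NaN
normals — flagged, never fabricated). Orientation is either "up"
(non-negative z) or toward a viewpoint. The upward convention makes
negative M3C2 distances read as movement with gravity.

**Local-plane projection (denoising).** Before any surface-path
computation, measured clouds are optionally projected point-by-point
onto the total-least-squares plane of their 16 nearest neighbours. Only
the normal component of each point's offset is removed, so silhouettes,
widths and in-plane positions are untouched. The reason is quantitative:
path lengths measured over noisy samples are biased upward — an edge of
length ℓ between points with isotropic noise σ has expected length
≈ ℓ·(1 + 2σ²/ℓ²), which at σ = 0.3 mm and ℓ ≈ 1 mm inflates geodesics
by several percent. The projection removes that bias at the cost of a
curvature flattening of order r²/(2R) (neighbourhood radius r, surface
curvature radius R) — ≈ 0.1 mm for r ≈ 2 mm on a 15 mm curl, negligible
against the traits measured. This is a first-order local plane fit
performed inside the trait pipeline, not a general smoothing pass, and
it can be disabled (`extract_leaf_traits(..., denoise=False)`).

## Geodesic distances

Three methods are implemented; all operate on a triangle mesh, and raw
clouds are first triangulated by **local tangent-plane Delaunay**: each
point's 12 nearest neighbours are projected onto its PCA tangent plane,
triangulated in 2D, and the triangles incident to the point are kept
(deduplicated globally). This is the construction point-cloud heat
solvers use, and it degrades gracefully: where the cloud is locally 1-D
(a polyline) no faces are produced and the solver falls back to graph
distances.

1. **`unfold` (default).** Dijkstra over the mesh edge graph gives a
   guaranteed upper bound on the polyhedral geodesic distance. Jacobi
   sweeps of a *virtual-source* triangle update then relax it: for each
   face, the distances at two corners define a circular wavefront from a
   virtual point source in the face's plane; if the straight segment
   from that source to the third corner crosses the shared edge, its
   length is a candidate distance (otherwise the corner routes
   `a + |edge|` apply). The update is exact for a point source on flat
   geometry, so the fixed point reproduces flat-surface distances to
   machine precision, and it handles cut loci correctly — the far side
   of a 10 mm cylinder evaluates to π·10 mm within 0.02%, where
   smoothing-based estimators lose several percent. Sweeps stop when the
   largest change drops below 10⁻⁶ mm (cap 200).
2. **`heat`.** The heat method: one backward-Euler diffusion step
   (t = mean-edge-length², cotangent Laplacian, lumped mass), normalize
   the negative gradient, then a Poisson solve for the distance
   potential; Neumann and Dirichlet diffusion solutions are averaged on
   meshes with boundary. Retained because it is the classical tool for
   this task and useful for cross-checking, but it undershoots near cut
   loci (≈ 3% on the cylinder test), which is why it is not the default.
3. **`graph`.** Plain Dijkstra on the symmetrized 12-NN graph. A strict
   upper bound with a known chordal distortion (up to ~8% on regular
   samplings); used as the independent oracle in tests and as the
   fallback for untriangulable clouds.

Every returned distance is clamped from below by the Euclidean distance
to the source (a true lower bound for any geodesic) and points in
components not containing the source are ∞. Because the default solver
is strictly more accurate than the graph oracle, the test suite asserts
the *one-sided* relations — Euclid ≤ ours ≤ graph — plus closed-form
values on flat, cylindrical and polyline geometries, rather than
symmetric agreement with the biased oracle.

## Hulls, projected area, meshing

Convex hulls use Qhull (scipy); degenerate (rank < 3) inputs return
volume 0 with a flag and the planar hull area, so flat fixtures pass
through plant-scale code. An independent check recomputes the volume as
the summed Delaunay tetrahedra. The projected canopy area is the 2D
alpha shape of the xy-projection: Delaunay triangles with circumradius
≤ α are kept and their areas summed (they partition the hull, so no
union bookkeeping is needed); α → ∞ reproduces the convex hull and the
area is monotone in α. Default α = 5 × the projection's mean
nearest-neighbour spacing — the printed projected-area benchmark of the
reference model depends on an unstated α, so exact reproduction of that
one figure is not promised.

Surface meshing for leaf-area summation projects the cloud onto its
best-fit plane, Delaunay-triangulates there, and culls triangles whose
circumradius exceeds the largest probe radius (default
{1.5, 3, 6} × mean NN spacing) or whose area is below the sliver
threshold. Mesh vertices are exactly the input points and the area is
Σ ½‖(b−a)×(c−a)‖. The projection step assumes the blade is a single
sheet over its best-fit plane — true for aligned sugar beet blades with
realistic droop and curl, wrong for surfaces that fold back on
themselves (see Limitations).

## Leaf trait pipeline

Alignment rotates about z only (the vertical must survive, because
inclination is measured against it): the longitudinal axis is the first
principal component of the xy spread, with a fallback for steep, wide
leaves whose footprint is nearly isotropic (xy eigenvalue ratio > 0.6):
there the 3D principal axis — the midrib direction — is projected to xy
instead. If that too is ambiguous the function asks for a manual
transform, mirroring the manual alignment of reference-model practice.
The petiole end is placed at lower x by a mass argument: the blade
carries most of the surface area, hence most points, so the median x
must lie tip-ward of the extent midpoint.

The width profile walks 1.0-mm x-slabs. Within a slab the longitudinal
slope is first removed (a line z ~ x fitted and subtracted) — on a
steeply rising petiole the z-spread across the slab otherwise leaks
into the transverse curve and inflates its arc length. Points are then
binned by y (bin width = half the segment), the highest point per bin
forms the top surface, a degree-3 polynomial z = p(y) is fitted, and
the width is the arc length of p over the occupied y-range (a chord
would undercount curled sections). Slabs with fewer than degree+1 bins
fall back to the y-extent and are flagged.

The blade base is the first post-warm-up segment (warm-up 5) whose
width exceeds 2.5 × the running mean of all widths seen so far, where
the running mean is the interquartile mean (mean of the central 50%).
The trimmed mean is what makes the 2.5 factor usable: a single 2× noise
spike is trimmed away, and the first blade segments entering the series
sit in the upper quartile and do not immediately drag the baseline up.
Its keypoint is placed at the slab midpoint in x, the midpoint of the
occupied y-range, at the local top surface z.

Leaf length is the geodesic distance from the petiole base to its
farthest surface point (the tip); blade length is the geodesic from the
blade-base keypoint (snapped to the nearest cloud point) to the tip and
is clipped to the leaf length. Blade width takes, per 1-mm slab of the
blade, the geodesic between the slab's extreme-y boundary points — a
half-cylinder blade of radius 15 mm measures π·15 ≈ 47 mm, not the
30 mm chord — and reports the maximum over slabs. Each slab query runs
on the sub-mesh within 6 mm of the slab, which contains the
cross-section geodesic for realistic curls and keeps the cost linear in
the number of slabs. Blade area meshes the points tip-ward of the
blade-base x (the cut orthogonal to the longitudinal axis) and sums the
triangles. All stages record status flags: a constant-width object
reports leaf length and a distinguishable "no blade base found".

## Registration and M3C2

Point-to-plane ICP minimizes Σ((T·p − q)·n_q)² with a linearized
Gauss–Newton step per iteration, nearest-neighbour correspondences
gated at `max_correspondence_mm` (no normal-compatibility rejection),
and convergence on relative RMSE change (10⁻⁸, cap 50 iterations).
Optional region masks restrict correspondences to a rigid subset — the
beet body — so a plant whose leaves have sagged can still be registered
by its stable core; the estimated transform applies to the whole cloud.

M3C2 distances: at each core point (every reference point by default) a
normal is estimated from reference points within D/2 (default
D = 10 mm) and oriented upward; both clouds' points inside the search
cylinder (radius 5 mm, half-depth 50 mm) are projected onto the normal,
and the distance is the mean projection of the compared cloud minus
that of the reference. Core points with fewer than 4 contributors in
either cloud are invalid (NaN, never zero-filled). The level-of-detection
significance machinery of the original formulation is intentionally
omitted — only distances and their standard deviations are reported.
The scales are exposed because the appropriate values are data-dependent
and the reference analyses do not state theirs; figure-level deviation
maps are therefore reproduced qualitatively, while correctness is
guaranteed by an exact brute-force oracle on small clouds, zero
distances on identical clouds, and exact plane-offset recovery.

The sensor report averages per-leaf M3C2 σ and the *absolute*
voxel-count percentage differences: a sensor that over-samples one leaf
and under-samples another is not complete on average.

## Synthetic plants

A leaf is a parametric surface: the midrib's tangent angle from
vertical ramps linearly from a 12° take-off to `droop_deg` along the
petiole and stays at `droop_deg` through the blade, so the inclination
(blade base → tip vs vertical) equals the droop by construction and the
midrib is genuinely curved (arc ≠ chord). Cross-sections orthogonal to
the midrib are circular arcs of arc-length w(s): the petiole a flat
strip of constant width, the blade `w(u) = W·sin(πu)^k`, curled by
`cross_curvature`·π radians. The default exponent k ≈ 0.08 makes the
blade reach near-full width within a few millimetres of the junction —
the abrupt cordate shoulder of a sugar beet blade, and the geometry the
width-jump detector is designed for; gentler shoulders (larger k) make
the junction genuinely ambiguous (see Limitations). Ground truth is
computed by numerical integration of the same parametrization at 0.1 mm
steps (lengths) and a 0.1 mm × w/100 parametric grid (blade area); a
flat k = 1 blade reproduces the closed form L·W·2/π within 0.5%.

Sampling is uniform by area: the parametric surface is triangulated at
~1.2 mm, triangles drawn with area weights, barycentric points
perturbed by isotropic Gaussian noise (default σ = 0.3 mm, a realistic
close-range laser scan; density default 1 point/mm²). A plant is a
spheroidal body (semi-axes a, a, 0.7a, truncated below −0.3a) with
leaves attached at the crown at their azimuths, labels 0 (body) and
1..N (leaves); plant height/width truth comes from a dense noiseless
sampling of the union. Occlusion is modelled either as spherical-flip
hidden-point removal from a viewpoint or as a contiguous patch dropout
(the fraction·N nearest neighbours of a random centre).

The generator emulates geometry, sampling noise and occlusion. It does
not emulate sensor-specific artifacts (ghost points, mixed pixels,
reflectance-dependent dropout), soil/pot clutter, touching neighbour
plants, or segmentation errors — recovery results on it bound the
algorithmic error, not the full field error budget.

## Validation studies and problem sizes

`validation.leaf_recovery_study` draws 50 leaves (total lengths
~120–350 mm, blade widths ~28–100 mm, droop 25–110°, curl 0–0.5π,
σ = 0.3 mm, ~3,000–15,000 points each) and scores the full pipeline
against truth; `plant_recovery_study` does the same for 20 eight-leaf
plants at 0.3 points/mm². Typical medians: leaf length and blade width
well under 1% absolute relative error, blade area ~1.3%, inclination
~0.4°, blade-base localization ~1 mm. The hardest cases are steep
(droop < 30°) heavily curled leaves, where the blade shoulder curls
backwards past the junction and the trigger can fire a few millimetres
early (worst observed ≈ 6.5 mm); localization is therefore summarized
by its median. These sizes keep the whole study a few minutes on one
CPU; they are stated here because every reported error is conditional
on them.

## Numerical conventions

* Ties in argmin/argmax (petiole base, farthest point) break to the
  lowest index.
* Summary rounding is half away from zero at the printed precision;
  means of absolute values are used for all "mean deviation" rows.
* Degenerate inputs prefer flagged results over exceptions where a
  downstream consumer can continue (degenerate hulls, fallback width
  segments, invalid M3C2 cores); exceptions carry the failing stage.
* Percent deviations always use the benchmark as denominator.

## Known limitations

* Leaf alignment is automatic PCA; genuinely isotropic leaves require a
  manual transform, as in reference practice.
* The blade-base definition (width-jump factor 2.5) assumes an abrupt
  blade shoulder; on species or stages with gradually widening blades
  the junction is ill-defined and the trigger fires late by design.
* `mesh_surface` is a single-sheet height-field triangulation; strongly
  folded blades would need a different reconstruction.
* The projected-area benchmark depends on an unstated alpha parameter;
  only its qualitative behaviour (monotone in α, hull in the limit) is
  guaranteed.
* M3C2 here omits registration-uncertainty/LoD terms; σ values are raw
  standard deviations of valid distances.
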