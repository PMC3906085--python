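# Methods

This note documents the models, algorithms and numerical choices behind
`vessel_csa`, in the order the pipeline runs them, together with what the
synthetic phantoms do and do not establish about real coronary CT data.

## Problem setting

Contrast-enhanced coronary CT angiography (CCTA) renders the arterial lumen
as a bright tube (here ~450 HU) against soft tissue (~50 HU), blurred by the
scanner point-spread function (PSF) and corrupted by quantum noise. The
quantity of clinical interest is the lumen **cross-sectional area** (CSA, in
mm²) as a function of arc length along the vessel, because diseased lumens
are not circular and diameter-based measures understate or overstate
stenosis severity depending on the cut. The pipeline therefore measures CSA
*shape-free*: as the area of the polygon where a plane normal to the vessel
centerline intersects the reconstructed lumen surface. The companion
diameter is the **largest inscribed circle** of that polygon, which is
robust to crescent and slit-like lumens where an equivalent-circle diameter
is misleading.

## Synthetic phantoms (module `phantom`)

Every quantitative claim in the test suite is made against tubes with
analytic ground truth:

* **Centerline models**: straight line, circular arc, helix (radius,
  pitch, turns) — the helix exercises out-of-plane curvature and torsion.
* **Cross-sections**: circle(r), ellipse(a, b), crescent(R, r, offset) —
  the crescent (a disk with a second disk bitten out of its rim) is the
  canonical non-convex diseased-lumen shape. Its area follows from the
  two-circle lens formula; its inscribed-circle diameter has the closed
  form `R + offset − r` (the optimal circle sits on the symmetry axis
  opposite the bite).
* **Stenosis**: the cross-section is scaled so that area follows
  `A(s) = A₀ · (1 − depth · exp(−(s−s₀)²/2w²))`, a Gaussian dip with
  fractional depth and width in mm (default w = 3 mm).
* **Calcification**: an optional spherical high-HU insert (default 900 HU)
  offset radially from the axis.

Rendering: the lumen indicator is evaluated on a 3×-supersampled grid and
block-averaged (partial-volume fractions at the wall), mapped to HU,
convolved with an isotropic Gaussian PSF, then corrupted with additive white
Gaussian noise from a seeded generator. Defaults — 0.4 mm isotropic voxels,
450/50/900 HU, PSF σ = 0.6 mm, noise σ = 20 HU — sit in the typical CCTA
regime and are treated as the study conditions throughout; ground truth is
analytic and untouched by blur or noise.

What the phantoms do *not* emulate: beam hardening, helical reconstruction
artifacts, motion, contrast-density gradients, bifurcations, and spatially
correlated reconstruction noise (the added noise is white, which is *harsher*
than real CT noise at the voxel scale). Passing phantom tests therefore
demonstrates correctness of the geometry chain under known physics, not
clinical accuracy.

## Preprocessing (module `preprocess`)

* **Wiener deconvolution** against an explicit Gaussian PSF (σ in mm,
  default 0.6): `H*(f) / (|H(f)|² + nsr)` on the reflect-padded FFT.
  The default noise-to-signal power ratio 0.002 follows from
  (noise σ / lumen-background contrast)² = (20/400)² ≈ 0.0025. With
  `nsr = 0` the filter degenerates to the exact inverse, which is the unit
  test's oracle on noiseless, compactly supported inputs; note that at
  σ ≳ 1 voxel the 3-D corner of the frequency cube makes the pure inverse
  numerically explosive, so the inverse-limit check is run at σ = 0.3 mm.
  Deconvolution matters quantitatively: the half-maximum surface of a
  blurred cylinder sits inward of the true wall by ≈ σ²/2R (curvature
  bias, ≈ −9% area for r = 2 mm at σ = 0.6 mm); restoring the edge removes
  most of that bias.
* **Selective deblurring**: the deconvolved image is blended into the
  original only around high-HU structures (weight ramps linearly over a
  50 HU band below the threshold, then grey-dilated one voxel), so the
  soft-tissue background does not inherit amplified noise. The output is a
  voxelwise convex combination of the two inputs.
* **Bilateral filtering**: truncated-window (2σ_spatial), anisotropy-aware
  (mm converted to voxels per axis); with σ_range → ∞ it reduces exactly to
  a truncated Gaussian, which is its unit-test limit. It is available in
  the pipeline but off by default: on the deconvolved phantom data it
  re-introduces the convex-edge shrinkage that deconvolution just removed.

## Segmentation (module `segmentation`)

Seeds are connected components of a high threshold (default 350 HU), one
seed per component at the interior maximum of the distance transform —
contrast is most stable near the axis. Growth is breadth-first with the
acceptance rule *HU closer to the lumen feature-center than to the
background feature-center*, where the feature-centers are the two side-means
of an Otsu split of a local histogram (10 HU bins) pooled over spheres
(radius 2 mm) placed on the **region boundary**. Two implementation choices
matter and were driven by measurement:

* The histogram must be sampled at the boundary, not at the region centroid:
  a 2 mm sphere centered on the axis of a 2 mm-radius vessel sees only
  lumen, its Otsu split is degenerate (~430 HU on the phantoms) and growth
  stalls far short of the wall.
* Growth is iterated to a **fixed point**: centers are frozen during each
  BFS pass and refreshed from the full new boundary between passes, until
  the mask stops changing (a Picard iteration). Updating centers mid-BFS
  leaves voxels permanently rejected under early, biased centers — measured
  as a −10% area ratchet — and makes the result depend on seed placement;
  the fixed point is reproducible and seed-position-invariant.
* Otsu's between-class variance is flat across the empty gap between two
  well-separated modes; the split is taken at the middle of that plateau so
  it lands mid-gap rather than hugging the background mode.

Calcium (> 700 HU, applied to the *original* calibrated volume — the
deconvolved one can overshoot past any threshold) is relabeled and its
boundary refined to the surface of maximal gradient magnitude along rays
from the component centroid, counteracting blooming. Calcific voxels are
excluded from the lumen mask and reported separately. Manual include /
exclude masks are set operations with exclude winning.

## Surface (module `mesh`)

Marching Cubes (topologically consistent Lewiner variant, via
scikit-image) at iso 0.5 on the binary mask, or at a mid-wall HU level on
the preprocessed volume restricted to the dilated mask. The pipeline
defaults to the HU route: the binary route quantizes the wall to the voxel
grid (profile nRMSE 3.5–4.9% on default tube phantoms, single-section dips
to −12%), while iso-surfacing the restored HU field interpolates the wall at
sub-voxel positions (nRMSE 2.4–2.9%). Smoothing is Taubin λ/μ
(λ = 0.5, ν = 0.53, 20 iterations): unlike plain Laplacian smoothing it does
not shrink the tube, which would bias every CSA low (measured volume change
< 1%).

## Centerline (modules `thinning`, `centerline`)

The curve skeleton is computed by **sequential homotopic thinning**: a
border voxel is deletable iff it is a *simple point* (its removal preserves
both foreground 26-connectivity and background 6-connectivity in the 3³
neighborhood — the Malandain–Bertrand characterization, memoized on 26-bit
neighborhood configurations), and deletion proceeds in increasing
distance-transform order with lexicographic tie-breaks, so layers peel
symmetrically and the survivor hugs the medial axis. Curve endpoints (single
foreground neighbor) are preserved only when they sit on the local distance
plateau; shallower endpoints are surface whiskers and keep eroding.
Interior cavities (noise pockets below threshold inside the lumen) are
filled before thinning — a contrast-filled lumen is solid, and homotopic
thinning would otherwise faithfully preserve every pocket as a closed
medial surface.

The skeleton graph (26-adjacency, Euclidean edge weights) is pruned to a
single path: terminal chains are trimmed from each leaf until the chain
regains half of its peak distance-to-boundary — a bump branch is shallow
throughout and vanishes up to its junction, a true vessel run only sheds
its whisker tip — then the graph-diameter path (longest shortest-path
between leaves, deterministic tie-breaks) is taken, and finally each end is
retracted to where the vessel regains ≥ 90% of its typical (75th-percentile)
caliber, because the distance field within one radius of a cut face is
cap-limited and the skeleton there is untrustworthy.

Jaggedness removal is two-stage, all in continuous coordinates: a
moving-average (window 5, shrinking symmetrically at the ends so endpoints
are preserved exactly), then **overlapping local cubic Béziers**: windows of
4 consecutive points advancing by 2 (50% overlap), each window's curve
sampled densely and cross-faded linearly where two windows cover the same
stretch. Control points need not lie on the curve — that is what lets the
fit cut through the staircase — while the locality prevents the global
over-smoothing a single high-order fit would cause. The composite is
arc-length reparameterized; tangents are central differences. On default
noisy phantoms this yields RMS distance to the analytic axis of ≈ 0.2–0.3
voxels (raw thinned path: 0.4–0.5), i.e. genuinely sub-voxel.

## Cross-sectional area (module `csa`)

At each resampled station (default 0.25 mm) the plane through the
centerline point with the tangent as normal is intersected with the surface
(trimesh plane sectioning); of the resulting closed loops, the one
containing the centerline point (innermost on ties) is the lumen contour.
Area is the shoelace sum on the contour's best-fit plane —
orientation-free, no shape assumption. The inscribed-circle diameter is
solved by a grid at 1/20 of the equivalent radius followed by Nelder–Mead
refinement of the signed distance-to-boundary from up to three
well-separated near-optimal grid cells (a non-convex contour can hold
several competing pockets; single-start refinement was measured to miss the
global optimum by up to 2.5% on crescent contours). Stations within 1.5 mm
of the centerline ends are skipped (cap slivers). A plane is *deviated*
when it crosses a neighbor inside the lumen (plane–plane intersection line
closer to either center than the local equivalent radius) or its area jumps
> 30% against both neighbors; deviated planes are repaired by interpolating
center and normal from valid neighbors and re-slicing, up to 3 rounds, then
excluded with a flag.

## Validation statistics (module `validation`)

Reference series are IVUS-style pullback tables (per-frame position, max /
min / mean lumen diameter, lumen area) or phantom truth. Alignment is by
arc length with a user-supplied landmark offset; the CT profile — the
coarser series — is linearly interpolated at the reference positions.
Statistics: signed per-point percent error `(A_ref − A_CT)/A_ref·100`
(the signed mean and the mean of absolute values are both reported, the
absolute one as headline), RMSE normalized to the reference mean (%), and
the OLS fit of CT on reference read against the identity line. On phantom
runs the pipeline aligns by geometry instead (each section center projects
onto the true centerline), so skeleton end-retraction cannot shift the
stenosis between the two series.

## Determinism

Identical configuration and seed reproduce every artifact byte-for-byte:
the only random source is the phantom noise generator (seeded), all
iterations have fixed order (lexicographic voxel order in BFS and thinning,
deterministic tie-breaks in path search), and CSVs are written with a fixed
float format.

## Problem sizes

The shipped tests and the acceptance script run on grids of roughly
48×48×64–80 voxels (0.4 mm spacing, vessels of 2 mm radius and 21–28 mm
length) — sizes at which every stage's behavior is already asymptotic while
a full pipeline run takes ~2 s.

## Known limitations

* Per-section CSA accuracy under the default 20 HU white noise is bounded
  by the data itself: an independent per-slice oracle (polar ray sampling
  of the half-level crossing on the deconvolved volume) shows ±5–7% errors
  from restoration-amplified noise blobs, and the pipeline's worst sections
  match those locations. Profile-level statistics (nRMSE ≈ 3%) average this
  out; single sections cannot, without shape or smoothness priors this
  package deliberately avoids.
* Single branch-free vessels only; bifurcations must be removed upstream
  (manual masks or the automatic branch pruning).
* The PSF is user-declared, never estimated; a mis-stated σ shifts the
  wall systematically.
* Crescent concavities narrower than the PSF fill in physically; measured
  crescent areas run high by the corresponding amount (≈ +9% at the default
  geometry). This is a physics limit, not an algorithmic one — the
  inscribed-circle solver itself agrees with a brute-force oracle to < 1%.
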