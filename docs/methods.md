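# Methods

## The problem

Freehand 3D ultrasound acquires arbitrarily oriented 2D B-mode planes,
each tagged with the probe's 6-DOF pose from a position sensor.  Volume
quantification from such data needs three things to work together: a
segmentation of the target boundary in every plane, a mapping of those
boundaries into a common 3D frame, and — when planes come from more
than one acoustic window — recovery of the rigid misalignment caused by
subject movement between the window acquisitions.  `fus3d` implements
that chain and validates it on synthetic tracked-probe phantoms whose
geometry (hence volume) is known analytically.

Because plane sampling is sparse and anisotropic, each 2D plane is
segmented independently; no 3D segmentation is attempted.

## Hybrid GVF geodesic-active-contour segmentation

The front is the zero level set of φ(x, y, t), initialized as the exact
signed Euclidean distance to a user/seed polygon (negative inside), and
evolved by

    ∂φ/∂t = g ε κ |∇φ| + (1 − s) β₁ (u,v)·(−∇φ) + s β₂ ∇g·∇φ

* `f = (|∇(G_σ * I)| / α)²` is the edge map and `g = 1/(1+f)` the edge
  indicator (≈1 in homogeneous regions, →0 on edges).
* κ is the curvature from central differences; the term `g ε κ |∇φ|` is
  edge-gated curve-shortening regularization.
* (u, v) is the gradient vector flow of the edge map: the minimizer of
  `∬ μ|∇u|² + μ|∇v|² + |∇f|²·|(u,v) − ∇f|²`, computed by explicit
  diffusion and unit-normalized, so β₁ alone sets the advection
  strength.  GVF gives the force a capture range far beyond the edge's
  gradient support, which is what permits rough, free-form seeds.
* `s` is a global switch, initially 0 and latched to 1 the first time
  the average of `f` over the current zero level set (pixels with
  |φ| < 0.5) reaches `T_res`.  After the switch the advection velocity
  is −β₂∇g, the classic geodesic-active-contour attraction that
  descends `g` into the edge valley.  A front driven by ∇g cannot pass
  weak-edge gaps toward distant structures, which is precisely the
  leakage failure mode of a pure GVF drive.  No balloon (normal
  expansion) term is used.

One sign choice deserves note: written with velocity conventions, the
second-stage advection must *descend* g (velocity −∇g) for the front to
be attracted to edges; the implementation uses that attraction form.

The switch is treated as a single global scalar per iteration, latched
permanently once triggered.  A per-pixel switch would oscillate on
speckle and contradicts the definition of the trigger as one average
over the zero set.

### Discretization and numerics

* Advection terms use Godunov upwind differencing; curvature uses
  central differences with κ clipped to ±1 grid unit; time stepping is
  explicit Euler with dt = min(dt_max, 0.45 / (max|V_x| + max|V_y| +
  4 ε max g)), which keeps every per-iteration update below one grid
  unit (CFL safety).
* φ is rebuilt every `reinit_every` = 20 iterations as the exact
  distance to the sub-pixel marching-squares zero contour (KD-tree
  query), keeping |∇φ| ≈ 1 near the front.  This replaces fast-marching
  redistancing: near the band, distance-to-extracted-contour is exact
  and cheaper at these image sizes.
* Stopping: the net front drift between consecutive redistanced
  snapshots — mean |Δφ| per pixel per iteration over the |φ| < 3 band —
  falls below `stop_tol` = 1e-3, or `max_iters` = 500.  Drift is
  measured between snapshots because at force equilibrium the explicit
  scheme retains bounded per-iteration jitter that never reaches any
  tight per-step tolerance.  The test applies in both stages: a
  stationary pre-switch front is a settled GVF equilibrium whose
  zero-set average of f can no longer grow.
* GVF: μ = 0.2, 80 iterations, dt at the stability bound min(1/(4μ), 1);
  the diffusion runs on f normalized to [0, 1] (the explicit scheme's
  data term requires dt·|∇f|² ≤ 1, and only the field's direction is
  used downstream).  `compute_gvf` rejects dt above the μ-bound and
  reports divergence with the iteration index.
* Boundary conditions are reflective (Neumann) everywhere, so image
  borders exert no spurious attraction.

### Parameters

| name | meaning | default | note |
|---|---|---|---|
| ε | curvature weight | 0.8 | empirical set; grid-optimizable |
| β₁ = β₂ | advection weights | 6 | empirical set; grid-optimizable |
| T_res | switch threshold on ⟨f⟩ | 50 | empirical set; grid-optimizable |
| α | edge strength scale | 2.0 | sets f ≈ O(10²) on true edges and O(1–10) on smoothed speckle for 8-bit images |
| σ | Gaussian smoothing | 2 px | |
| μ, n_iter | GVF regularization / iterations | 0.2, 80 | standard GVF practice |

The (ε, β, T_res) defaults are the empirical working point that the
grid search shows to sit inside the flat low-error plateau (β ≳ 6ε) on
phantom-like images.  α has no published value for 8-bit data; it was
fixed once from the scale analysis above and is never tuned per run.

### Grid-search optimization

`optimize_params` segments one representative frame from one fixed seed
for every triple of the logarithmic grids

    T_res ∈ {5, 20, 50, 125.6, 315.5, 792.4, 1990.5, 5000}
    ε ∈ {0.1, 0.21, 0.46, 1, 2.15, 4.64, 10, 21.54, 46.42, 100}
    β ∈ {0.6, 1.29, 2.79, 6, 12.92, 27.85, 60, 129.27, 278.5, 600}

and scores each run by Hausdorff distance or MAD against the reference
boundary (failed cells get infinite error).  The error surface near its
minimum is a plateau; criterion differences under about half a pixel
are contour-extraction noise.  Cells within 0.5 px of the minimum are
therefore treated as equivalent and the cheapest equivalent cell is
selected — smallest T_res (the switch fires earlier, so evolution is
shorter), then smallest β, then smallest ε.  Selecting the strict
argmin instead occasionally lands in the never-switch region (T_res too
high for ⟨f⟩ to reach), which can score well on a single frame but
generalizes poorly across a sweep.  The full surface is returned for
inspection.

## Boundary metrics

Hausdorff distance (max of the two directed max–min distances) and
symmetric MAD (mean closest-point distance, averaged over both
directions) are computed after arc-length-uniform resampling of both
contours to 256 points, removing vertex-density bias, and scaled to mm.
Relative volume error is the signed percentage 100·(est − truth)/truth.

## Reconstruction and volume estimation

Wall surfaces: the filled segmentation mask minus its erosion by a
disk of radius 4–8 px (4 by default) gives a boundary ring; ring pixels
map through each frame's pose (pixel spacing → mm, then the rigid pose)
into a 3D point set per view.  Points are splatted into an isotropic
Cartesian grid (counts per voxel) and Gaussian-smoothed (σ = 1 voxel):
the smoothing turns the binary shell into a continuous intensity field
whose gradients the registration objective needs.  Fusion resamples
every view's volume into the reference grid (trilinear) and averages
where at least one view contributes.

Volume: each contoured plane contributes its in-plane signed-distance
field (negative inside, exact to ~1e-3 px; samples kept up to a 3 mm
outside band), mapped into the reference frame with the view's
registration transform.  A 3D signed-distance field is interpolated at
the voxel centers of a 0.5 mm grid by normalized inverse-distance
weighting of the k = 4 nearest plane samples; voxels with negative
interpolated distance count as interior, and the volume is the voxel
count times the voxel volume.  For a dense parallel stack this reduces
to a Cavalieri sum; for sparse multi-view geometries it blends the
planes' evidence smoothly.  Its known artifact: beyond the last plane
of a sweep, IDW extrapolates the nearest section outward as a cylinder,
so single-view estimates carry an end-cap bias that a second,
orthogonal view removes — single-view reconstructions missing the
object's extremes is exactly the failure mode multi-view acquisition
exists to fix.

## Coarse-to-fine registration

Views are registered pairwise to the reference view (the one with the
most segmented planes; ties broken by wall-point count).

1. **Hotelling initialization.**  Each wall point set gets a principal
   frame (centroid + covariance eigenvectors, descending eigenvalues).
   The moving frame is aligned to the reference frame under all four
   right-handed eigenvector sign combinations; each candidate is scored
   by the overlap MSE on the smoothed wall volumes and the best is
   kept.  Near-equal eigenvalues (within 10%) set a degeneracy flag —
   the corresponding axes are arbitrary and only the objective
   disambiguates.
2. **Levenberg–Marquardt refinement.**  Residuals are
   `I_R(T(q_j)) − I_N(q_j)` over the moving wall points, with `I_R`
   trilinearly interpolated in the reference volume and `I_N` the
   moving view's own smoothed rasterization sampled once per point.
   The 6 parameters are ZYX Euler angles about the moving centroid plus
   a translation (rotating about the centroid decorrelates rotation and
   translation).  Points mapping outside the reference grid contribute
   the background value 0 — equivalent to exclusion, since the volumes
   are zero-padded wall fields — and the in-grid count is reported as
   `n_overlap` (a floor of 100 voxels aborts the registration).  Two LM
   passes are run: all points on 1 mm voxels, then a strided ≤4000-point
   subsample on 0.5 mm voxels, which removes most of the voxel-binning
   bias of the coarse pass at a fraction of its cost.  LM stops on
   ftol/xtol = 1e-9 or 60 iterations; trilinear residuals are only
   piecewise smooth, so the iteration cap, not the step tolerance, is
   the effective stop.

A geometric caveat measured during development: for a single ellipsoid
of revolution the registration problem is ill-posed up to the object's
own symmetry group.  Symmetry transforms map the wall surface onto
itself, so volume estimates are unaffected (a deliberately "flipped"
recovery changed a two-view volume by +0.2%), but rotation-recovery
error is meaningless.  Motion-recovery studies therefore use a scene
with two unequal eggs — matching the physical calibration phantom,
which contains two egg objects — where the problem is well-posed.

## The synthetic phantom: what it emulates and what it does not

`phantom.make_phantom_frames` renders ellipsoid cross-sections under
exact plane poses: interior 150, background 60 (8-bit), Gaussian edge
blur of 0.6 mm, multiplicative unit-mean Rayleigh speckle with 0.8 px
correlation grain, optional weak-edge arcs (the edge response inside an
angular arc is blended toward a 4× blurred version, attenuation 0 = no
edge), an optional hyperechoic rim, and fan or parallel sweep
geometries with smooth pose sequences.  The analytic plane–ellipsoid
intersection supplies exact truth contours (the conic of the ellipsoid
restricted to the plane), so ground truth is available per frame to
machine precision.

Rendering choices worth recording:

* The default rim amplitude is 0.  A Gaussian rim centered on the
  boundary adds its gradient to the step's gradient *outside* the
  interface and cancels it *inside*, displacing the composite gradient
  peak outward — a contour perfectly locked to the image edge would
  then be biased relative to the geometric truth by construction.  A
  crisp rimless interface matches a water-tank calibration phantom;
  the rim field remains available for harder fixtures.
* Speckle is first-order only (multiplicative Rayleigh on the
  reflectivity, correlated, quantized to 8 bits).  There is no
  point-spread-function simulation, no attenuation/TGC, no shadowing,
  no cardiac motion.  Consequently, passing tests demonstrate the
  pipeline's geometric and numerical correctness and its robustness to
  first-order speckle, weak edges and subject motion — not performance
  on clinical image texture.
* Standard sweeps cover 85% of the phantom extent along the sweep
  normal: grazing sections (< ~5 mm radius) are not acquired in
  practice and segment unreliably; the multi-view configurations always
  include an orthogonal view that covers the tips in-plane.

## Study sizes

The validation studies run at desk scale: 88×88 px frames at 0.5 mm/px,
20 planes per view for the multi-view volume studies (40 per sweep for
the segmentation-accuracy study), inter-view motions up to 15° / 10 mm
(20° / 15 mm in the registration recovery study, 100 trials), and a
3×4×4 logarithmic sub-grid of the full 8×10×10 optimization grids for
the per-study parameter search.  The full grids remain the defaults of
`ParamGrid` and run in a few minutes on a single frame.

## Known limitations

* The global, latched switch trades adaptivity for stability: once
  fired, distant parts of the front that are still traveling lose the
  long-range force.  Middle-frame seeding plus neighbor propagation
  keeps fronts near boundaries, so this rarely matters in sequences.
* Speckle induces a small inward bias (~0.1 mm) in the equilibrium
  front position on multiplicative-noise images — noise power scales
  with intensity, so the edge-map ridge is slightly asymmetric.  This
  is visible as volume errors of −1 to −3% in fully automatic
  multi-view runs.
* The IDW volume estimator cannot extrapolate a tapering surface beyond
  the last plane of a sweep (cylinder end-caps); single-view estimates
  of elongated objects along their long axis are correspondingly poor.
* Registration assumes partial overlap of the wall surfaces and rigid
  inter-view motion; there is no deformable model.
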