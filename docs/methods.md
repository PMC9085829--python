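# Methods

`glomorph` quantifies glomerular morphology in light-sheet volumes of
optically cleared kidneys, and the quality of the clearing itself.  This
note documents the models, the parameters that matter, the synthetic data
the tests run on, and the numerical choices made where the procedure was
genuinely open.

## Conventions

Arrays are indexed `(z, y, x)`, 0-based.  The world position of voxel
`(i, j, k)` is `(i·dz, j·dy, k·dx)` µm; the physical extent of an axis is
`(n − 1) × spacing`.  Mesh vertices live in the same `(z, y, x)` µm frame
(PLY files map them to the conventional `x, y, z` properties).  All
lengths and diameters are µm, volumes µm³.

## Detection chain (`segment`)

A raw stack (typically 4 µm z steps, ~1 µm in plane) passes through:

1. **Isotropic interpolation** — linear resampling along z to the finest
   in-plane spacing.  Linear (order-1) interpolation is used because it
   cannot overshoot on blob edges; the z extent is preserved exactly and
   the new spacing is carried in the output's metadata, so every
   downstream feature is reported in true µm.
2. **Otsu binarization** — one global threshold maximizing between-class
   variance.  DiI-labelled structures are bright, so foreground is the
   upper class by default (`bright_foreground=False` flips it).
3. **Geodesic active contour** — a morphological GAC evolves the Otsu
   mask against an inverse-Gaussian-gradient edge map (pre-smoothing
   σ = 1 voxel, `alpha = 100`, 20 iterations, curvature smoothing 1).
   The balloon force defaults to **zero**: the initial mask already sits
   near the intensity boundary, and experiments on tube phantoms showed a
   shrinking balloon erodes ~0.2 µm of a vessel's radius per iteration
   whenever the discrete edge response fails to stall it, eventually
   severing thin necks.  The balloon remains a parameter for masks that
   start far from the edges.
4. **Instance separation with an ellipsoid-fit gate** — the Euclidean
   distance transform of the mask is smoothed (σ = 2 µm) and its
   h-maxima regions (prominence ≥ 1 µm) seed a watershed on the negative
   distance map.  H-maxima rather than point maxima matter for tubes,
   whose distance ridge is flat: a ridge becomes one marker instead of
   none.  Each watershed candidate is fitted with its second-moment
   ellipsoid (a uniform ellipsoid has covariance `diag(a², b², c²)/5`).
   Candidates are kept only if
   * fit residual `1 − IoU(candidate, fitted ellipsoid)` ≤ 0.3,
   * principal axis ratio ≤ 3 (rejects vessel segments),
   * volume ≥ `min_volume` (5000 µm³ at full scale).
   The residual gate of 0.3 was set from the observed separation between
   glomerular candidates (≈ 0.1–0.2, the neck stub accounts for the
   excess) and watershed fragments of vessels (≳ 0.3).
5. **Edge exclusion** — instances with any voxel within a margin of a
   stack face are dropped (default margin 5 % of the smallest axis
   extent), standing in for the interactive proofreading that confines
   analysis to the centre of the organ, where light-sheet data are
   reliable.
6. **Random sampling** — up to 10 instances per volume are drawn
   uniformly without replacement under a seed, mirroring the practice of
   analysing ten randomly selected glomeruli per kidney.

## Meshing (`meshing`)

Marching cubes runs on the **binary** instance field at iso-level 0.5 (the
segmentation already encodes the boundary decision; meshing the intensity
field would let neighbouring structures bleed into the surface).  Vertices
are scaled to µm.  Smoothing is explicit discrete curvature flow: each
vertex moves by `step` times its umbrella Laplacian (neighbour mean minus
itself), 10 iterations at step 0.1 by default — chosen so a sphere's
volume drifts < 5 % (enforced by test); a step that inverts triangles
aborts with advice to reduce it.  Open boundary loops (e.g. where a neck
was cut) are closed by fan triangulation against the loop centroid, then
normals are re-oriented outward.  Enclosed volume is the signed sum of
origin-tetrahedra over triangles — exact for watertight meshes,
translation-invariant by construction, and cross-checked in the tests
against an independent z-ray-parity voxelization oracle.

## Morphometry (`morphometry`)

A glomerulus is a round **head** on a vascular **neck**.  Three anchor
points define its frame:

* **central base point** — centroid of the open boundary loop where the
  instance was cut from its attachment (cached before hole closing); for
  meshes arriving closed, the centre of the face set nearest a supplied
  reference point.  The pipeline derives that reference from the label
  field: the voxels where the instance touches the rest of the segmented
  foreground.  An isolated instance falls back to the thinner end of its
  principal axis.
* **centroid** — volume centroid of the closed mesh (divergence theorem).
* **tip** — the mesh vertex farthest from the base.

Orientation is the unit vector base → centroid.  Vertices are binned into
steps of fixed height along this axis (default 2× the in-plane voxel
size, tying profile resolution to sampling); each step's cross-section is
summarized by the exact max/min Feret (rotating-calipers) widths of its
vertices projected onto the plane normal to the axis.  Empty steps are
kept as explicit gaps.

* `L` — arc length of the polyline through consecutive non-empty step
  centres, base to tip.
* `hMax`, `hMin` — max and min Feret width of the single thickest step in
  the centroid→tip span (ties broken toward the centroid).  An
  alternative reading — extremes over the whole head span — is available
  as `head_mode="span_minmax"` but is not the default.
* `nMax` — largest step width in the neck span.  The neck ends at the
  **waist**: the narrowest step strictly between the base and the
  thickest head step (widths within 5 % of the minimum count as ties, and
  the waist is placed at the head end of the tied run, so a noisy
  constant-width neck is spanned whole).  Steps behind the base
  (`t < 0`, the closure cap) and steps with fewer than 3 vertices
  (slivers) are excluded.  A fixed-fraction alternative
  (`neck_mode="fraction"`, neck = base → 0.8× centroid projection) is
  provided; it is not the default because with glomerular proportions
  (head semi-axis comparable to neck length) a fixed fraction reaches
  into the lower head and reports head widths as neck widths.

All scalar features are rotation- and translation-invariant up to mesh
resolution (tested at 1 %).

## Clearing metrics (`metrics`)

* **Linear expansion** = √(post area / pre area) of the thresholded
  tissue silhouette; the areal ratio is used for titration comparisons.
  Identities (square law, composition) hold to 1e-9.
* **Grid transmittance** = 100 × mean inner-grid / mean outer-grid line
  intensity, with optional intensity inversion for bright-field images;
  **spectral transmittance** = 100 × sample/blank per wavelength.
* **Fluorescence retention** = (S_day − B_day)/(S₀ − B₀); day 0 is 1 by
  construction.
* **SNR profile** — at each depth, five randomly chosen dendrites are
  profiled along a line perpendicular to the local axis (length 5× the
  dendrite width).  The core is the central half-width, the flanks the
  surroundings beyond 1.5× the width; both are summarized by medians,
  the robust analogue of a human picking clean regions (insensitive to a
  neighbouring dendrite crossing the line).  SNR = core/flank, so it is
  1 when the signal vanishes; `(core − flank)/flank` is available by
  flag.  The exact formula behind published SNR numbers is generally not
  recoverable from methods text; this definition is logged in output
  metadata and is a package decision, not a literature value.
* **Tortuosity** d/D = polyline arc length over endpoint distance (≥ 1).
* **Rigid alignment** — coarse rotation grid search, translation by
  phase correlation, scored by normalized cross-correlation; below a
  correlation floor the identity is returned with a warning.
* **SSIM** — both images are Otsu-binarized, then the standard SSIM
  (11-pixel Gaussian window, σ 1.5, K₁ = 0.01, K₂ = 0.03, range 1) is
  averaged over the map.

## Statistics (`stats`)

Two groups: two-sample t-test, Welch by default (the pooled variant is a
flag) — Welch is the safer default when the variant is unspecified and
group variances differ.  Shapiro–Wilk normality is computed per group and
annotated, never acted on (no silent switch to nonparametric tests).
Three or more groups: one-way ANOVA followed by Tukey's HSD.  Stars:
`***` p < 0.001, `**` p < 0.01, `*` p < 0.05, else `ns`.  Degenerate
identical-constant groups report p = 1.

`run_cohort_experiment` generates a paired normal/disease cohort (the
disease arm scales head semi-axes and neck radius by the effect factors),
pushes every volume through the full chain, pools per-glomerulus features
per arm, compares each feature, and reports recovery diagnostics
(estimated vs ground-truth effect ratios).  Volumes that fail a stage are
skipped and counted.

## Synthetic phantoms (`synthetic`)

The kidney phantom renders ellipsoidal heads joined by cylindrical necks
to short perpendicular "parent vessels", plus an optional random
capsule-walk vessel network, on an anisotropic grid.  Rendering is
partial-volume accurate: boundary voxels are refined on a 4³ subgrid, so
a noise-free ellipsoid's integrated coverage matches its analytic volume
within 2 % even at 2 voxels per semi-axis.  The PSF is an isotropic
Gaussian in µm applied as a per-axis sigma on the anisotropic grid
(σ_vox = σ/spacing) — numerically equivalent at these scales to
rendering fine and downsampling, at a quarter of the memory.  Noise is
optional Poisson followed by additive Gaussian.  Placement is
collision-aware (heads avoid each other, existing necks and vessels;
parent vessels steer away from other heads) so the instance ground truth
stays unambiguous; an overcrowded spec fails validation with an explicit
message.  Everything derives from one integer seed: identical seeds give
bit-identical volumes and tables.

Full-scale defaults model a mouse kidney imaged at 4 µm z-steps: head
semi-axes 30 ± 3 µm (glomerular diameters ≈ 60–70 µm), neck radius
8 ± 0.8 µm, neck length 40 ± 5 µm, 8:6:1 head:vessel:background contrast,
PSF σ 1.5 µm, Gaussian noise SD 20 (≈ 3 % of head intensity).  No
intensity statistics for DiI-labelled kidneys are published, so the
contrast values are free parameters of the phantom, not literature
calibrations.

Repeated cohort simulations use a **reduced regime**
(`glomorph.presets`): (20, 64, 64) voxels at (4, 2, 2) µm, two glomeruli
per volume, head semi-axes 14 ± 1.4 µm, neck radius 6 ± 0.6 µm.  The
sizes were chosen once so the thinnest structure still spans three
in-plane voxels (below that, neck diameters are not resolvable) and one
volume analyses in well under a second, making 200-replicate null
calibrations and 20-seed power runs practical.

2D fixtures: a lobed tissue silhouette on a printed grid whose post image
scales all radii by a factor (area ratio = factor² up to rasterization);
a grid with a central sample region attenuating the inner lines by a
known fraction; fluorescence planes carrying ≥ 5 circular-arc dendrites
whose core/background ratio follows a depth schedule and whose
centrelines (arc length and chord) are recorded.  Dendrites are placed
with a minimum separation of 3× their width so the flanks of one profile
are not contaminated by a neighbour.

### What the phantoms do not emulate

Light-sheet stripe artifacts, depth-dependent attenuation (beyond the
dendrite SNR schedule), anisotropic PSFs, autofluorescence texture,
vascular network realism, multi-channel imaging, and deformation of the
organ itself.  Passing tests therefore demonstrate that the *computation*
is correct and well-calibrated on data matching its assumptions — not
that detection would be artifact-free on real acquisitions, where the
interactive-proofreading surrogate (edge exclusion + fit gates) carries
more weight.

## Numerical choices and degenerate inputs

* Otsu refuses constant volumes; GAC refuses empty initial masks and
  logs (rather than hides) a collapsed result.
* Feret widths: single point → (0, 0); two points → (distance, 0);
  collinear sets → min width 0.
* Mesh volume refuses non-watertight input; hole filling refuses
  non-manifold boundaries and more than 8 loops.
* The thickest-step tie-break (toward the centroid) and the waist
  tie-break (toward the head) make the profile features deterministic.
* Seeds: cohort per-volume seeds are spawned from the master seed via
  `numpy` `SeedSequence`, all below 2³¹.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run: one full-scale
sphere-on-neck recovery (40 × 128 × 128 at (4, 1, 1) µm), a 20-seed power
experiment at 18 vs 10 pooled glomeruli with head/neck ×1.3, and a
null calibration (200 replicates in the tests, 100 in the script) at 2
volumes per arm — all in the reduced regime above, chosen as the
smallest sizes at which necks remain resolvable and the statistics are
informative.

## Known limitations

Recovered volumes at the reduced scale are biased ≈ −8 % (threshold and
smoothing erosion at 2–4 µm voxels); the bias is common to both cohort
arms and cancels in the comparisons.  nMax is the noisiest feature
(neck radii span only ~3 voxels at reduced scale).  The base-point
fallback for isolated closed meshes (thin-end heuristic) can mis-orient
nearly spherical objects without necks.  `align_rigid`'s rotation grid
search is coarse by design; sub-degree registration is out of scope.
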