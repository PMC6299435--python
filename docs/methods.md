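# Methods

## Scope and model of the data

`aortamorph` quantifies transverse morphology of a single-tube arterial
segment (the ascending aorta) in 3D phase-contrast microCT stacks of
paraffin-embedded, unpressurised vessels.  The intensity model is
layered and ordered: luminal and external paraffin are darkest, the
interlamellar medial matrix and adventitia are intermediate, and the
elastic lamellae are brightest.  The tunica intima produces no
contrast, so the innermost lamella (IEL) forms the lumen–wall boundary.
All physical outputs are in µm/µm² through a single isotropic voxel
size (default 1.1 µm).  Branch points are out of scope; one vessel per
slice is assumed.

## Pipeline

1. **Wall binarisation.** Per slice: Otsu threshold, morphological
   closing then opening (disk, default radius 3 px), largest bright
   8-connected component, hole filling restricted to holes smaller than
   the lumen candidate (the largest enclosed hole).  Otsu makes the
   step invariant to affine intensity rescaling.  Artefacts are handled
   by exclusion masks (pixels forced to background) rather than manual
   painting.
2. **Lumen.** The 4-connected background cavity enclosed by the wall;
   if it reaches the image border the wall is open and the slice is
   routed to the dilated-vessel fallback.  The lumen contour is
   extracted at subpixel precision (marching squares) and ordered by
   angle about the centroid.
3. **Media–adventitia limit.** Distance maps d_in (to the lumen) and
   d_out (to the outer background) define the mid-wall line as the
   band |d_in − d_out| ≤ 0.5 px (an exact-equality set would be empty
   on a grid).  The minimum wall thickness is min(d_in + d_out) on that
   line, per slice.  The inner wall half (d_in < d_out, plus the line)
   is dilated by a Euclidean disk of radius round(0.35 × min thickness)
   and intersected with the wall; the limit's polar radius profile is
   then smoothed with a periodic cubic smoothing spline and the media
   mask regenerated from it.  The 0.35 factor is a strain- and
   age-specific calibration; it is config-exposed
   (`media_dilation_factor`) and validated here only for the phantom
   family, whose true media boundary is constructed at radial depth
   (0.5 + 0.35) × wall thickness so that the rule is exact and recovery
   errors are attributable to the pipeline.
4. **Lamellae.** Thresholding inside the media mask only; components
   < 10 px removed.  Default threshold is isodata (Ridler–Calvard, the
   midpoint of the class means): on two-level media with antialiased
   thin rings, Otsu settles well below the midpoint and systematically
   overcounts ring pixels, while the class-mean midpoint recovers
   partial-voxel coverage almost unbiasedly.  Otsu remains selectable
   (`lamellae_threshold_method`).
5. **Dilated-vessel fallback.** Non-circular cross-sections defeat the
   midline construction, so: top-quantile threshold (default brightest
   15 %) extracts the lamellar skeleton; a marker-based watershed on
   the *negated* distance-to-skeleton map (markers: a lumen seed and
   the image border) places basins in the lumen and outside, and its
   watershed line crosses ring gaps along their narrow waist, closing
   the tube — the classic binary-watershed gap closure.  The lumen is
   the enclosed region grown from the seed (the previous slice's
   centroid in pipeline runs), replacing interactive carving.  Gaps
   wider than ~90° of arc are not closable and raise a
   "manual mask required" error.  Fallback slices contribute diameter
   (and areas when a manual limit is supplied) but no thickness.
6. **Centreline and reslicing.** A cubic smoothing spline through the
   per-slice lumen centroids; the stack is resampled on planes
   orthogonal to the local tangent, spaced one voxel in arc length,
   centred on the centreline, with parallel-transported in-plane frames
   (no axial twist, so en-face break shapes are preserved).  Sampling
   is trilinear with edge extension (`mode="nearest"`); constant-value
   padding would poison global thresholds on the resliced slices.
   Without this stage, a tube tilted by α reads as an ellipse with axis
   ratio sec α; the mean-of-axes diameter is inflated by
   (1 + sec α)/2 − 1 (≈ 0.77 % at 10°).
7. **Virtual opening.** For each of K angular samples (default 720) a
   ray starts on the smoothed lumen contour and follows the outward
   curve normal; bilinear sampling at 1-px radial steps converts the
   annular wall into a (angle × depth) band with depth 0 at the
   lumen–wall limit.  Normals (rather than centroid rays) keep rays
   locally non-crossing for mildly wrinkled contours.
8. **Thickness.** Along the same normals, thickness is the extent of
   the first contiguous in-media run (bilinear mask sampling at 0.25-px
   steps).  The per-slice samples are histogrammed (Freedman–Diaconis)
   and a Gaussian is fitted by least squares to the bin counts,
   initialised at the sample moments; the fitted mean/SD are primary,
   sample moments are also reported.  Rays that never meet the media
   are dropped and counted; > 10 % dropped sets a warning flag.
9. **IEL surface and breaks.** The 1-px lumen–wall border is dilated by
   a Euclidean disk (default 7 px — calibrated for ~1.1 µm voxels and
   real wall geometry) and intersected with the wall; for each (slice,
   angle) the maximal intensity over shell voxels along the ray forms
   the en-face image.  Pixel areas use a per-slice arc pitch
   (2π × mean lumen radius / K × voxel), so axially varying calibre
   does not bias break areas.  Breaks are 8-connected components below
   a deliberately conservative seed threshold (default 0.75 × median
   surface grey — an intact surface must yield nothing), then re-grown
   to their local half-contrast boundary (midpoint of the component
   core and the surrounding bright reference), the usual half-maximum
   sizing convention.  A fixed threshold or a manual break mask (exact
   pass-through, mirroring manual delimitation) may replace detection.
   Components are not connected across the 0°/360° seam; a break
   straddling the seam would be reported as two regions (same total
   area).
10. **Statistics.** Per-sample (animal) means are compared pairwise by
    the two-sample KS test — D computed on the pooled support; p by
    exhaustive permutation enumeration when both n, m ≤ 10 (e.g. all
    C(10,5) = 252 splits for 5 vs 5), else the asymptotic Kolmogorov
    tail with the standard effective-n correction — and by a two-sided
    variance-ratio F-test (larger variance over smaller, one-sided tail
    doubled, capped at 1).  Flags: `***` p ≤ 0.001, `**` ≤ 0.01, `*`
    ≤ 0.05, `#` for 0.05 < p ≤ 0.08 (trend), boundaries inclusive.  No
    multiple-testing correction is applied, by design; the output table
    records the number of comparisons.  The F-test's normality
    assumption is fragile at n = 5; this is documented rather than
    "fixed" to keep parity with standard practice in the field.  The
    asymptotic KS tail is a poor approximation below n ≈ 20 (errors up
    to ~0.18 at n = 5); it is never used there — exact enumeration is.

## Manual overrides

A corrected media–adventitia contour on one slice replaces that slice's
polar radius profile exactly and propagates to neighbours as a
Gaussian-decaying delta (length `override_decay_slices`, default 10
slices), anchored exactly at every override slice.  A smoothing spline
through the anchors was considered and rejected: isolated anchors make
smoothing splines ring, violating the expectation that a local
correction decays monotonically with axial distance.  The Gaussian
kernel gives an exact fixed point for a no-op override, monotone decay,
and local convergence of far-apart anchors.

## The phantom generator

Each slice is rendered from the radial depth d = ρ − ρ_L(θ) measured
from the luminal boundary: lumen (d < 0, paraffin grey), media
(0 ≤ d < T_m, interlamellar grey with n bright rings of thickness t
centred at c_i = (i + ½)T_m/n), adventitia (T_m ≤ d < T_wall), paraffin
beyond.  Default greys 15000/30000/50000 (paraffin/matrix/lamellae)
with the adventitia at 28000, close to the matrix, as in phase-contrast
appearance.  The symmetric ring placement makes the lamellar area
fraction of a circular media exactly n·t/T_m.  Rendering is
piecewise-constant at `supersample`× resolution (default 4×) and
box-averaged, giving subpixel-accurate antialiased boundaries; masks
are coverage > 0.5.  Noise is additive Gaussian, clipped to the 16-bit
range and quantised to integers (so TIFF round trips are lossless);
`noise_sigma = 0` reproduces the clean phantom bit-identically for a
given spec and seed.

* **Tilt** is rendered as the true oblique section of a tilted
  cylinder: an ellipse with in-plane axis ratio sec α whose centre
  drifts tan α px/slice — so reslicing can be validated against the
  exact analytic cross-section.  Waviness (sinusoidal centreline) is
  rendered as pure shear, a good approximation for gentle amplitudes.
* **Wrinkles** displace all interfaces together
  (ρ_L → ρ_L + A sin fθ), preserving radial thickness and — exactly —
  all band areas of circular slices.
* **Dilations** scale the lumen radius by a raised-cosine ramp peaking
  at `max_scale` mid-window, optionally with an elliptical
  `axis_ratio`; wall thickness stays constant.
* **Breaks** replace the affected lamellae by matrix grey inside a
  slice/angle window, with ~2-px smooth edges.  Edge factors are
  min-combined and the axial profile uses a half-open pixel convention,
  so the rendered half-level set equals the analytic window of
  (end − start + 1) slices — the detection pipeline sizes breaks at
  half contrast, and truth and render must agree at that level.
  `through_wall` breaks cut the entire wall (an open vessel) to
  exercise the fallback.
* **Ground truth** comes from the generating radius functions, not the
  rendered pixels: circular slices in closed form, wrinkled/elliptical
  boundaries by midpoint-rule quadrature (4096 nodes; spectrally
  accurate for these smooth periodic integrands, < 1e−6 relative error
  against closed forms).  True thickness is undefined (NaN) on
  elliptical slices, mirroring the pipeline's refusal to measure
  thickness there.

What the phantom does *not* emulate: phase-retrieval artefacts, ring
artefacts, adventitial texture, intensity inhomogeneity, real lamellar
waviness in the radial direction, and partial-volume behaviour beyond
linear box averaging.  Passing recovery tests therefore demonstrates
correctness of the geometry and measurement chain under the stated
intensity model, not robustness to every acquisition artefact of real
scans; noise-robustness is only characterised as monotone degradation
with `noise_sigma`.

## Problem sizes and defaults

Validation runs use desk-scale stacks chosen to exercise every stage:
the recovery phantom is 64 slices of 512×512 (lumen r = 100 px, wall
40 px, 5 lamellae of 2.8 px → lamellar fraction 41.2 %, in the
wild-type range); the tilt phantom 48×384² at 10°; IEL-break phantoms
use the real-data wall scale (wall 82 px → media ≈ 77 µm at 1.1 µm
voxels) because the 7-px IEL dilation is calibrated to that geometry —
with a desk-scale wall the shell would span two lamellae and hide
single-lamella breaks.  The synthetic ageing cohort is 3 groups × 5
stacks (12 slices of 288², wall 24/26/28 px ± 3 % between-animal
jitter, noise σ = 300), the smallest configuration in which the
pipeline, pooled distributions and group statistics all operate as on
full-size data.  Full-size stacks (thousands of 4008×2672 slices) are
processed by the identical code path; the central analysis window
defaults to 200 slices.

## Numerical choices

* Connectivity: 8-connected foreground / 4-connected background in 2D.
* Structuring elements are Euclidean disks; the media dilation radius
  is rounded to the nearest integer pixel.
* Contour smoothing: periodic cubic smoothing spline with a per-sample
  residual budget of 0.5 px² — tracks amplitude-5 px, frequency-12
  wrinkles to < 1 px RMS while suppressing mask staircase noise.
* The minimum wall thickness for the 0.35 rule is taken per slice (the
  alternative, per stack, is a documented interpretation choice; the
  per-slice form adapts to axial taper).
* Degenerate inputs fail loudly with typed errors (empty slice, open
  wall, wall too thin, no contrast, fallback failed) and the pipeline
  degrades gracefully up to a configurable failed-slice fraction
  (default 20 %), recording per-slice provenance in the run manifest.
* Determinism: all randomness flows from explicit seeds; identical
  config + seed reproduce byte-identical CSV outputs.

## Known limitations

Single-tube segments only (no branch handling); fallback slices have no
automatic media–adventitia limit (a manual limit can be supplied);
break components do not merge across the angular seam; the Gaussian
histogram fit can be ill-conditioned for strongly non-Gaussian
thickness distributions (sample moments are reported alongside); the
0.35 media rule and 7-px IEL dilation are calibrations for this
tissue/resolution and must be re-validated for other strains, ages or
voxel sizes.
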