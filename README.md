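# aortamorph

3D micro-scale morphometry of the murine aortic wall from phase-contrast
microCT stacks.

Phase-contrast microCT resolves the layered structure of an unstained,
paraffin-embedded aorta — lumen, tunica media with its concentric
elastic lamellae, outer adventitia — throughout the whole vessel, at
~1 µm isotropic resolution.  `aortamorph` turns such tomogram stacks
into the standard histological read-outs without sectioning or
staining, for researchers quantifying vascular remodelling in ageing or
connective-tissue disease models (e.g. Marfan-syndrome mice):

* **Segmentation** — per-slice wall/lumen binarisation (Otsu), a
  media–adventitia limit derived from the Euclidean distance transform
  (the mid-wall line, equidistant from the wall–lumen and
  adventitia–paraffin limits, dilated by `0.35 × min wall thickness`),
  lamellae by greyscale thresholding inside the media, and a
  watershed-based fallback that closes the tube on non-circular
  (dilated) cross-sections.
* **Vessel geometry** — centreline through the lumen centroids (cubic
  smoothing spline), reslicing orthogonal to the vessel axis (parallel-
  transported frames, so oblique cuts become true transverse cuts), and
  "virtual opening": a local Cartesian→polar transform that straightens
  the annular wall using each lumen–wall boundary point as a local
  centre.
* **Morphometry** — per slice: lumen diameter `d = (a + b)/2` from a
  direct least-squares ellipse fit of the internal circumference (the
  echocardiographic convention); media thickness sampled along contour
  normals, histogrammed and fitted with a Gaussian; cross-sectional
  areas by pixel counting; lamellar fraction
  `100·|lamellae|/|media| %`.  Stack summaries are means ± SD over a
  central window (200 slices on full-size scans).
* **IEL surface** — the internal elastic lamina borders the lumen; its
  shell (lumen–wall border dilated by 7 px) is projected en face by
  maximal intensity along each unwrapping ray, and breaks — dark
  discontinuities on that surface — are detected, sized at their local
  half-contrast boundary, and reported as a percentage of the luminal
  surface.
* **Group statistics** — two-sample Kolmogorov–Smirnov test (exact
  permutation p for n,m ≤ 10, asymptotic otherwise) and a two-sided
  variance-ratio F-test of dispersion, flagged `*`/`**`/`***` at
  p ≤ 0.05/0.01/0.001 and `#` for the 0.05–0.08 trend band.

Because real synchrotron scans of this kind are rarely shareable, the
package ships a first-class **phantom generator**: synthetic aorta
stacks (wrinkled lumen, concentric lamellae, adventitial rim, tilt,
waviness, focal dilations, multi-slice lamellar breaks, noise) rendered
from signed radial coordinates with 4× supersampling, together with
closed-form/quadrature ground truth for every quantity the pipeline
measures.  The whole pipeline is validated by parameter recovery
against that analytic truth.

## Worked example

```python
from aortamorph import PhantomSpec, PipelineConfig
from aortamorph.pipeline import run_morphometry

spec = PhantomSpec()          # 64 slices, 512x512, 1.1 um voxels:
                              # lumen r=100 px, wall 40 px, 5 lamellae
cfg = PipelineConfig(central_window_n_slices=48)
run = run_morphometry(cfg, spec=spec)
print(run.summary.as_frame().round(2))
```

prints

```
                            mean   sd
lumen_diameter_um         220.41  0.0
media_thickness_um         37.22  0.0
media_area_um2          30124.16  0.0
lamellae_area_um2       12787.28  0.0
interlamellar_area_um2  17336.88  0.0
lamellae_pct               42.45  0.0
```

i.e. the pipeline recovers the analytic ground truth of this phantom
(diameter 220 µm, media thickness 37.4 µm, media area 30 243 µm²,
lamellar fraction 41.2 %) within 0.2 %, −0.5 %, −0.4 % and +1.3
percentage points respectively; the near-zero SDs reflect the
axially uniform tube.

The same pipeline runs from the shell on real TIFF stacks:

```sh
aortamorph phantom --output-dir ph/                 # make a demo stack
aortamorph morph --input ph/phantom.tif --output-dir out/ --no-reslice
aortamorph iel   --input ph/phantom.tif --output-dir out_iel/
aortamorph stats --input per_sample_means.csv --output comparisons.csv
```

`morph` writes `per_slice.csv`, `summary.csv`, `thickness_samples.csv`
and a run manifest (config snapshot, input checksums, per-slice
provenance: `auto` / `fallback` / `override`).

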