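# chorioconcord

Cross-modality lesion concordance for central serous chorioretinopathy
(CSC) imaging: quantifying how well choriocapillaris abnormalities seen on
swept-source OCT angiography (SS-OCTA) spatially correspond to the
choroidal hyperpermeability seen on indocyanine green angiography (ICGA).

The package is for imaging researchers who have en-face frames from both
modalities, manual lesion annotations (ImageJ ROIs or binary masks), and a
handful of matched landmarks — and who want reproducible, unit-correct
numbers out the other end: registration diagnostics, overlap indices,
lesion areas in mm², interobserver agreement, and longitudinal change
statistics. A built-in synthetic scene generator with exact ground truth
makes every stage testable without clinical images.

## The model

**Registration.** The ICGA frame (moving) is aligned to the OCTA
choriocapillaris frame (fixed) by a planar affine estimated from ≥ 3
user-specified landmark pairs:

```
[u]   [a00 a01 a02] [x]
[v] = [a10 a11 a12] [y]
                    [1]
```

Three non-collinear pairs determine the six coefficients exactly
(residuals vanish to machine precision); more pairs give the least-squares
fit. Annotations are transformed as polygons (vertex mapping), so areas
scale exactly by |det| of the linear part, and all overlap is measured on
the fixed OCTA pixel grid.

**Concordance.** Spatial agreement of two regions A, B on a common frame
is the Jaccard index

```
JI = |A ∩ B| / |A ∪ B|
```

computed two ways: RASTER (pixel-center counting on the frame lattice, the
reporting method — manual annotations are pixel-resolution objects) and
POLYGON (exact clipping of the continuous even-odd fills, the analytic
oracle). The same statistic measures interobserver agreement between two
graders of one frame.

**Lesion taxonomy.** OCTA choriocapillaris lesions: type A (coarse
granulated hyper-reflective area), type B (roundish dark halo around A),
type C (hypo-reflective spots inside A). ICGA: mid-phase
hyperfluorescence and early-phase hypofluorescence. Areas convert to mm²
through each frame's field of view.

**Longitudinal change.** Per (eye, lesion type): Δ = follow-up − baseline
area, with pooled baseline-vs-follow-up Wilcoxon signed-rank tests (exact
small-sample null, zeros dropped, midranks for ties) and a two-way
group × lesion-type ANOVA (type-II sums of squares) with per-type
Mann-Whitney companions for the laser-vs-observation contrast.

## Worked example

`examples/02_register_and_overlap.py` runs the full pipeline on one
synthetic eye — generate a ground-truthed paired scene, render both
frames, detect the landmark crosses, fit the affine, overlap the
annotations:

```
true type A area: 8.734 mm^2 (closed form)
landmark detection error: 0.073 px (worst)
affine fit from 3 landmarks, rmse 2.32e-12 px
cross-modality JI = 0.9563 (type A 8.732 mm^2 vs registered hyperfluorescence 8.448 mm^2)
```

The true lesion covers 8.734 mm² by construction; the measured polygon
area agrees to 0.02%. The affine interpolates the three detected
landmarks exactly (rmse ~ 1e-12 px), and with a deliberate 4 px
cross-modality boundary discrepancy the Jaccard index lands at 0.96 —
the shortfall from 1.0 is exactly that discrepancy plus raster
discretization. The other examples cover Jaccard basics
(half-overlapping unit squares → JI = 1/3), interobserver agreement
(JI 0.930 ± 0.017 at 4 px grader noise), a longitudinal cohort (radius
shrinkage 0.6 vs 0.8 → every lesion's relative area change recovered,
group effect p ≈ 1e-12), and ImageJ `.roi`/`.zip` round-trips.

A thin CLI wraps the same functions for shell use:

```bash
chorioconcord simulate --bundle-dir /tmp/demo --n-eyes 6 --seed 1
chorioconcord concordance --bundle-dir /tmp/demo --out-dir /tmp/demo-report
chorioconcord longitudinal --bundle-dir /tmp/demo --out-dir /tmp/demo-report
```

## Layout

- `src/chorioconcord/roi_model.py` — frames, lesion labels, ROIs, masks,
  even-odd rasterization, mask image I/O
- `src/chorioconcord/imagej.py` — ImageJ `.roi` / `.zip` binary codec
- `src/chorioconcord/registration.py` — landmark affine fit, point/ROI
  mapping, image warping, landmark CSV
- `src/chorioconcord/overlap.py` — Jaccard index, cross-modality and
  interobserver concordance, cohort summaries
- `src/chorioconcord/area_quant.py` — mm² measurement, summaries, paired
  tests (exact Wilcoxon in `_stats.py`)
- `src/chorioconcord/longitudinal.py` — change records, pooled paired
  tests, two-way group comparison
- `src/chorioconcord/synthetic.py` — ground-truthed paired scenes,
  simulated graders, cohorts, scene bundles
- `src/chorioconcord/pipeline.py` + `cli.py` — orchestration and CLI

See `docs/methods.md` for the full methodological account.
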