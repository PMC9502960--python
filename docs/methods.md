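# Methods

This note documents the conventions, models and numerical choices behind
chorioconcord, the assumptions they rest on, and what the synthetic
validation does and does not demonstrate about clinical data.

## Coordinate and rasterization conventions

All geometry lives in 0-based continuous pixel coordinates, x rightward,
y downward, with pixel centers at integer positions: pixel (row i, col j)
spans [j−0.5, j+0.5) × [i−0.5, i+0.5). A region's raster realization
marks cell (i, j) iff the point (x=j, y=i) lies inside the even-odd fill
of the polygon rings. The even-odd rule (a point is inside iff a ray
crosses the boundary an odd number of times) matches ImageJ's
composite-ROI semantics: interior rings punch holes regardless of
orientation, arbitrary nesting is handled by parity, and a multifocal
lesion is one ROI with several disjoint rings whose area is the sum.

The rasterizer is an exact scanline implementation of this rule: edges
are treated half-open in y (min y ≤ row < max y) so shared vertices count
once, and a crossing at x flips parity for all centers strictly right of
x (a center exactly on a crossing counts as inside). Continuous areas and
polygon clipping delegate to shapely; the even-odd fill is realised as
the symmetric difference of the rings' simple fills.

The polygon form of an annotation is authoritative; masks are derived.
When an ROI is transformed it is transformed as a polygon (vertex
mapping) and re-rasterized once at the end — never by warping masks,
which would compound two discretization errors.

Empirically, the pixel-center count converges to the continuous area
faster than the worst-case perimeter bound suggests: over random convex
polygons the mean relative discrepancy falls by ~3× (not just 2×) when
resolution doubles, consistent with ~h^1.5 error decay for smooth
boundaries. The test suite asserts the guaranteed direction (doubling
resolution at least halves the mean discrepancy, and the error never
exceeds the perimeter bound).

## ImageJ ROI format

The codec implements the documented `.roi` binary layout: big-endian,
64-byte header beginning `Iout`, vertex coordinates stored as
bounding-box-relative int16 plus (for modern writers) absolute float32
sub-pixel coordinates gated by the SUB_PIXEL_RESOLUTION option bit.
Multi-ring ROIs are written as composite (ShapeRoi) records — a float
path array of MOVETO/LINETO/CLOSE segments. Polygon, freehand, traced,
rectangle and oval records are read; line/point/angle/polyline types are
rejected by name since they have no area. Unknown header option bits are
ignored rather than rejected, because files in the wild vary by ImageJ
version. Round-trips are exact for integer vertices and float32-precise
(< 1e-3 px at frame scale) otherwise.

## Registration

Direction convention: ICGA is the moving frame, OCTA choriocapillaris
the fixed frame, and all overlap is computed on the OCTA pixel grid —
fixing one frame pins the mm² scale to a single device's field of view.
The affine has six free coefficients; with exactly three non-collinear
landmark pairs the linear system is square and the fit interpolates
(residuals at machine precision), with more pairs it is the least-squares
minimizer of Σ‖T(moving_i) − fixed_i‖². Three-pair fits therefore
reproduce the classical three-landmark procedure identically while the
API generalizes beyond it.

Degeneracy is detected explicitly: if the smallest singular value of the
centered moving-point matrix is below 1e-6 of the largest, the
configuration is declared collinear and rejected with the threshold named
in the error. Image warping (provided for visualization) is inverse
warping: each target pixel center is pulled through T⁻¹ and sampled with
bilinear (intensity) or nearest (mask) interpolation, zero-filled outside
the source.

## Overlap and agreement

JI = |A∩B| / |A∪B|. The RASTER method counts pixel centers on the fixed
frame — the primary reporting route, since manual annotations are
pixel-resolution objects — and the POLYGON method clips the continuous
fills exactly, serving as the independent oracle; the two agree within a
perimeter-per-resolution bound verified on random polygon pairs. An empty
union raises rather than returning 0: a missing lesion must surface
loudly, because JI is only meaningful where both annotations exist. The
POLYGON route sorts its two operands canonically before clipping so that
JI(A,B) and JI(B,A) are bitwise equal (polygon clipping is otherwise
symmetric only to the last ulp).

Interobserver agreement is the same statistic for two graders of one
frame, with no registration. Cohort summaries report mean ± sample SD
(n−1); a single eye reports SD 0 with an explicit n=1 flag.

## Areas and paired tests

Areas are measured on the continuous polygon fill and converted by the
frame's px→mm² factor (fov_width/width · fov_height/height). Summaries
use mean ± SD or median (IQR) with type-7 linearly interpolated
percentiles — the convention must be fixed somewhere for IQRs to be
reproducible, and type-7 is the numpy/R default.

The pipeline does not auto-select between Student's t and Wilcoxon: the
caller chooses, with Wilcoxon the default for areas (right-skewed in
practice). Auto-selection based on a normality pretest would hide a
methodological decision inside the pipeline.

The Wilcoxon signed-rank implementation follows a fixed, documented
policy: zero differences dropped (with the count reported), midranks for
tied |d|, exact two-sided p from the full sign-assignment null for
n ≤ 20 (computed by dynamic programming over doubled ranks, so midranks
stay integral — identical to enumerating all 2ⁿ assignments), and the
normal approximation with tie-corrected variance and 0.5 continuity
correction above. The exact route matches brute-force enumeration
exactly and scipy's exact mode in tie-free cases; its type-I error at
α = 0.05 calibrates to ~0.04–0.05 (slightly conservative, as a discrete
exact test must be).

## Longitudinal analysis

Baseline is visit 0; follow-up is each eye's latest visit (horizons vary
per eye and are recorded per record). One change record exists per
(eye, lesion type) present at both ends; anything else goes into an
explicit exclusion report. Relative change is Δ/baseline, flagged
undefined (NaN) at baseline 0 rather than silently dropped.

The laser-vs-observation contrast is a two-way factorial ANOVA on the raw
deltas with factors group and lesion type, type-II sums of squares (the
design is unbalanced in practice: unequal groups, halo missing in some
eyes), plus per-type Mann-Whitney tests as a rank-based companion. Both
are reported because "compare the median change between groups by ANOVA"
is not a single well-defined procedure — ANOVA compares means — and
reporting both covers either reading without guessing. Lesion types with
a group entirely absent are flagged and left out of the factorial model.
Under a simulated null the group-effect rejection rate at α = 0.05
calibrates to ~0.05.

## Synthetic scenes

The generator produces the geometry the clinical material exhibits, with
exact ground truth:

- **Type A**: star-convex boundary r(θ) = r₀(1 + Σₖ aₖ cos(kθ+φₖ)),
  default r₀ = 1.5 ± 0.3 mm, 4 harmonics with 1/k-damped amplitudes
  (closed-form area πr₀²(1 + Σ aₖ²/2)). The default radius makes baseline
  type A areas ~7 mm², the scale seen clinically.
- **Type B**: an annulus hugging the type A boundary (two even-odd
  rings), present with probability 0.821 — the clinical halo prevalence
  (32/39 eyes). Width 0.35 mm.
- **Type C**: small discs (default 4 × 0.16 mm radius) strictly inside
  type A.
- **ICGA side**: the hyperfluorescence region is type A mapped through
  the inverse of the true affine with a radial boundary discrepancy of
  scale `icga_boundary_sigma_px` (default 8 px — the modalities outline
  the same lesion imperfectly); hypofluorescence spots are the mapped
  type C discs shrunk by 0.6, strictly smaller, matching the clinical
  observation that OCTA reads the hypoperfusion larger than ICGA does.
- **Affine**: rotation ±10°, isotropic scale 0.9–1.1 about the frame
  center, translation ±30 px (centering keeps frame content mapping to
  frame content). Landmarks (default 3) are placed ≥ 0.2·frame apart
  with a minimum-triangle-area floor, so registration preconditions hold
  by construction, and are related across frames exactly by the affine.
- **Frames**: 1024×1024 px over 12×12 mm by default (the cropped en-face
  SS-OCT field exceeds the classical 6×6 mm protocol; both are presets).

Rendering gives each modality enough structure for landmark detection
and visual sanity, no more: elevated mean inside type A, suppressed
halo/spots, multiplicative speckle on OCTA, stronger blur and milder
noise on ICGA, and sub-pixel symmetric cross markers at the landmarks.
Markers are re-detected by matched-filter correlation with the zero-mean
cross template and quadratic sub-pixel peak refinement (worst observed
error ~0.2 px at default noise). No claim is made that the textures
match device output — the generator states its appearance parameters and
stops there.

Determinism: each scene derives two independent RNG streams (shape,
noise) from its seed by fixed spawn keys, so appearance can vary under
identical geometry; simulated graders get a third keyed stream per
grader index. Identical (params, seed) reproduce bit-identical
manifests, masks and images.

Simulated graders displace each boundary radially by a smooth Gaussian
field with 30° angular correlation (default σ 4 px), sharing one field
across the rings of an ROI so annuli deform coherently; σ = 0 reproduces
the truth exactly. Cohorts assign eyes to balanced laser/observation
groups and model follow-up as a per-group lesion radius factor (default
0.68 for both groups — the clinically observed ~0.46 area ratio, with no
built-in group difference).

## What the synthetic validation shows — and does not

Passing the end-to-end checks demonstrates that the measurement chain is
correct: landmark detection to sub-pixel accuracy, affine recovery to
1e-9 on exact input and ~1% linear / 0.5 px central translation from
rendered frames, JI ≥ 0.99 when the two modalities truly coincide, JI
degrading monotonically with the built-in boundary discrepancy, exact
recovery of known area changes, and correctly calibrated test sizes. It
does not validate the clinical annotation process itself: real graders
have structured (not radially Gaussian) disagreement, real lesions are
not star-convex, device artifacts and segmentation errors are absent,
and the true inter-modality correspondence in patients is unknown.
Clinical overlap values therefore cannot be predicted from these
simulations — only measured by the same machinery.

## Problem sizes

The shipped validation uses the sizes its statistical claims need and no
more: 100 random polygon pairs for oracle equivalence, 200 random
transforms for exact affine recovery, 50 seeds per boundary-sigma level
for the monotonicity sweep, 2000 replicates for each test-size
calibration, and 100 replicates of 40-eye cohorts for power checks.
Calibration and power simulations run on polygon geometry alone (no
rendering), which is why they are cheap; the rendered pipeline checks use
the full 1024² frames.

## Known limitations

- No automatic lesion segmentation: annotations come from humans (or the
  simulator). No intensity-based or nonrigid registration.
- Curved ImageJ shape segments (quad/cubic) are rejected, not flattened.
- The grader adjudication step of clinical practice is out of scope; the
  pipeline accepts a designated consensus annotation instead.
- Empty-union JI, all-zero-difference Wilcoxon and single-group ANOVA are
  errors by design; callers who want silent NaNs must catch them.
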