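# Methods

## Measurement model

The quantity of interest is the percentage of *flow voids* — pixels of the
binarized en-face CC angiogram below a local threshold — in three regions
defined relative to the GA lesion, and its association with the
square-root-transformed yearly growth rate of the lesion.

### Compensation

SD-OCTA signal at the CC is attenuated by whatever sits above it; drusen
darken the structural CC slab and the flow slab in the same columns. The
compensation step forms `flow ⊙ G(1 − structure)` with `G` a truncated
Gaussian blur, on intensities normalized to [0, 1] (inputs of 8/16-bit
depth are divided by their nominal maxima on load, making the definition
bit-depth independent). "3 × 3 Gaussian" is realized as σ = 0.85 px,
truncated to 3 × 3 and renormalized — the σ that common 3 × 3 Gaussian
approximations use; both σ and the kernel size are configurable. The
product is min–max rescaled to [0, 1] by default; rescaling makes the
subsequent binarization invariant to the global gain the multiplication
introduces, and is exposed as a flag (`rescale=False` preserves the raw
product) since either convention is defensible. A constant product
(constant structure *and* flow) makes min–max undefined; the flow image is
then returned unchanged.

The multiplicative inversion is a first-order correction, exact when the
local structural level is 0.5: for a shadow factor `(1 − x)` applied to
both channels, the compensated gain is `(1 − x)(1 + x) = 1 − x²`. The
synthetic generator sets its structural base level to 0.5 for precisely
this reason (see below); on real data the correction is approximate and the
locally adaptive threshold absorbs most of the residual.

### Binarization

Phansalkar's local threshold, designed for low-contrast images:

    t = m · (1 + p·e^(−q·m) + k·(s/R − 1))

with `m`, `s` the mean and population SD over a **circular** window
(matching the ImageJ Auto Local Threshold convention) of radius 15 px at
1024 px / 6 mm (~88 µm), reflective (edge-repeating) padding at borders,
and the original constants p = 2, q = 10, k = 0.25, R = 0.5. Only the
radius is protocol-specific; all five are configurable. A pixel is a void
iff its value is strictly below `t`. The implementation computes windowed
sums with `scipy.ndimage.correlate` (variance as E[x²] − E[x]², clipped at
zero); the test suite holds it pixel-exactly equal to a direct per-pixel
brute-force computation.

When the analysis grid is scaled down (see Problem sizes), the radius is
scaled with it to keep the physical window size: 8 px at 512 px / 6 mm
(~94 µm), 4 px at 256. The 6-eye mean of each FV metric moves by less than
0.15 percentage points between 256 and 512 px grids.

### Regions

The Euclidean distance transform (pixel centers, exact EDT, scaled to µm)
of the background from the **union** of all lesion foci defines ring
membership on half-open intervals: para-atrophy (0, 500] µm, peri-atrophy
(500, 1000] µm. Computing the distance from the union automatically
excludes ground covered by adjacent foci, and the half-open convention
prevents double counting (the protocol literature specifies "500 µm-wide
rings" without a boundary convention). `FV_OUT` is computed over *all*
non-lesion pixels, rings included; the variant that excludes both rings is
also computed (`fv_out_beyond`) and selectable, since the published
definition does not state which was used. Focus labeling uses
8-connectivity (the ImageJ particle default); the fovea distance of a
multifocal lesion is the unweighted mean of per-focus centroid distances.

### Growth rate

`yGR = (√A₂ − √A₁)/FU` in mm/yr removes the dependence of raw area growth
on baseline size. Negative growth (segmentation jitter in real data) is
retained and flagged, not clamped — truncation would bias cohort means.
Eyes whose lesion touches the outermost pixel ring at either visit are
flagged and excluded from cohort statistics: their growth cannot be
measured on the scan.

### Statistics

Eyes cluster within patients (1–2 per patient), so regression of yGR on the
candidate covariates (age, baseline area, fovea distance, FV_OUT, FV_500,
FV_1000, ΔFV) uses GEE: Gaussian family, identity link, exchangeable
working correlation (the standard choice at 1–2 eyes per patient;
configurable), robust sandwich SEs (the GEE convention; a Mancl–DeRouen
bias-reduced covariance is available via `cov_type="bias_reduced"`).
Candidates with p < 0.05 in the univariable screen enter one multivariable
model. Because ΔFV ≡ FV_500 − FV_1000, a screen that admits all three
produces an exactly singular design; the multivariable stage therefore
admits covariates in order of univariable significance and drops any that
are collinear with those already admitted, recording the drops. No
multiple-testing correction is applied across the seven candidates — this
mirrors the screening convention the protocol follows, and is a known
limitation of that convention rather than of the implementation.

With every cluster of size 1, the GEE estimates coincide with OLS (tested
to 1e-6). With ~20 clusters, sandwich SEs are anticonservative: in
record-level null simulations the 5%-level univariable screen fires in
~12% of 40-eye/20-patient cohorts, against ~3–6% at 200 eyes/100 patients.
The type-I-error validation therefore runs at 200 eyes/100 patients (the
same size as the slope-recovery check); small-cohort inference should
prefer the bias-reduced covariance.

Inter-grader repeatability uses ICC(2,1) — two-way random effects, absolute
agreement, single measure (via `pingouin`), the form appropriate when the
same two graders measure all eyes and absolute agreement is the question;
ICC(3,1) is selectable. Pearson correlations come from the product-moment
formula with the t-transform p-value.

## Synthetic cohort generator

The generator's role is to emulate the statistical structure the analysis
assumes, with known ground truth:

- **Void-probability field.** `P = base + g·(d_fovea/500 µm) + e·taper`,
  clipped to [0.01, 0.99]: base void fraction 0.42; eccentricity gradient
  g = −0.008 per 500 µm (voids decline away from the fovea, the reported
  physiologic magnitude in older eyes); per-eye ring excess
  `e ~ U[0, 0.10]` at full strength within 500 µm of the lesion edge,
  tapering linearly to zero at 1000 µm. The two-ring protocol observes only
  the ring means, so the taper profile is a modeling stand-in, not a claim
  about real lesions. Under the lesion itself P = 0.9 (CC flow under
  atrophy is largely absent); those pixels never enter the metrics.
- **Texture.** Difference-of-Gaussians-filtered white noise (grain 30 µm,
  the CC lobule scale at the macula) mapped through the normal CDF to a
  uniform field `u`; a pixel is a void iff `u < P`, so the realized void
  fraction tracks `P` directly (tested to ±1 percentage point per region).
  Flow intensity is bimodal (0.15 in voids, 0.70 in perfused texture, plus
  N(0, 0.04) noise) — separated enough that the local threshold recovers
  the partition, which is what makes truth recovery testable.
- **Drusen.** Poisson-placed hard discs (1/mm², radius 60 ± 15 µm) with
  Gaussian-feathered edges; the shadow `(1 − depth·f)`, depth 0.30,
  multiplies *both* channels. The structural base level away from drusen is
  0.5, which makes the multiplicative compensation exact to first order in
  the shadow depth (residual gain `1 − x²`); the compensated void fraction
  under drusen footprints matches the drusen-free reference within a
  fraction of a point even at depth 0.5.
- **Lesions and growth.** 1–3 elliptical foci (P = 0.7/0.2/0.1), total
  baseline area lognormal(ln 0.8, 1.0) clipped to [0.1, 8] mm² (median
  ~0.8 mm² with a heavy right tail, as GA cohorts show), centered near the
  fovea (offset SD 0.55 mm). The follow-up mask is the baseline mask
  dilated isotropically by `speed × FU` via the distance transform, with
  `speed = 0.02 + 4.0·e + N(0, 0.03)` mm/yr floored at 0 and
  `FU ~ N(1.31, 0.2)` yr floored at the 12-month eligibility minimum. The
  coupling of 4 mm/yr per unit excess is the injected effect the pipeline
  must recover; with it, the synthetic mean yGR (~0.43 mm/yr) sits above
  typical clinical cohorts (~0.23 mm/yr) — the generator favors a
  detectable effect over calibrated cohort means, and the recovery tests
  quantify the former.
- **Determinism.** One RNG stream per eye, spawned from
  `SeedSequence(seed)`; identical seeds give bit-identical images and
  tables (tested), independent of cohort-level parallelization.

`simulate_eye_records` draws per-eye *measurements* directly (expected
measured ΔFV = 50·e percentage points from the taper geometry, ring-scale
sampling noise ~1.2 points, a shared within-patient speed component) for
studies that need hundreds of cohorts — e.g. the type-I-error check — where
rendering images would add nothing.

What the generator does **not** emulate: OCTA decorrelation physics and
projection artifacts, motion artifacts, B-scan-level segmentation error,
irregular (non-elliptical, non-isotropically-growing) lesion shapes, and
grader variability in mask delineation. Passing recovery tests therefore
shows the measurement chain is correct and well-calibrated on data obeying
its assumptions — not that those assumptions hold on any particular
device's scans.

## Problem sizes

The clinical protocol's grid is 1024 px / 6 mm; the shipped study scripts,
the acceptance run and the heavier tests sample the same 6 mm field at
512 px (window radius scaled to match physically), which keeps a 40-eye
cohort under ~10 s without moving the metrics (< 0.15-point mean FV shift,
see above). Unit fixtures use 128–256 px. The type-I study uses 200
record-level cohorts.

## Known limitations

- The compensation is the standard first-order multiplicative correction;
  severe shadowing (depth near 1) is not invertible and is not modeled.
- Exchangeable GEE at ~20 clusters is anticonservative with sandwich SEs
  (quantified above).
- The published per-eye database behind the original cohort statistics is
  not redistributable here; `ccflow.stats.replicate_cohort` recomputes all
  cohort summaries, correlations and the GEE table from such a per-eye
  file when one is supplied (`data/s1_per_eye_database.xlsx`), and the
  corresponding acceptance test can only run where that file is present.
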