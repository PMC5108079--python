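# Methods

This note documents the models and procedures implemented in `septalge`,
the defaults they ship with, and the design choices made where the problem
left the design genuinely open.

## Segmentation model

STRM (signal threshold versus reference mean) flags a myocardial voxel as
hyperenhanced when its signal strictly exceeds `mean + k·sd` of a remote
reference ROI. Choices:

- **Strict inequality** at both STRM and manual thresholds. Equality is
  excluded, consistent with reading ">kSD" literally; on continuous image
  data the measure-zero boundary is immaterial, but the contract matters
  for integer-valued test fixtures.
- **Sample SD** (n−1 denominator) over the remote ROI, **pooled across
  slices** into a single global mean/SD — one reference region, one
  threshold. Per-slice referencing can be emulated by calling
  `remote_stats`/`strm_segment` slice by slice.
- **No despeckling or minimum component size.** The raw thresholded mask is
  the result; any morphological post-filter would change the burden
  statistics and is left to the caller.
- The septal and total percentages share the **total LV mass** denominator,
  so septal % is always ≤ total %.

## Septal region geometry

The septum is the myocardial sector between, and inclusive of, the two RV
insertion points, with each border extended a configurable distance
(default 10 mm) beyond the point of contact. Two ambiguities had to be
resolved:

- **Extension metric.** The 10 mm is interpreted as arc length along the
  mid-wall circumference, i.e. an angular extension of `10 / r_mid`
  radians, where `r_mid` is the mean of the average endo- and epicardial
  vertex radii about the epicardial centroid. A myocardial sector border is
  a radial line, so pushing it "x mm along the wall" is the natural
  reading; a Euclidean chord would differ only in the third decimal at
  clinical radii. The parameter `extension_mm` is exposed throughout.
- **Which arc is the septum.** Two insertion points split the wall into two
  arcs. The minor arc (< 180°) is taken; at exactly 180° the arc traversed
  counterclockwise from the first to the second annotated point is used.
  With physiological insertion-point placement the septal arc is always
  the minor one.

Angles are measured about the epicardial-contour centroid. Insertion points
missing on a slice are propagated from the nearest annotated slice (logged
at INFO). Voxel membership is by centre-point inclusion with no
partial-volume weighting, matching the binary thresholding downstream; the
discretization error this causes is bounded by the region's perimeter in
voxels. An extension so large that the two extended borders meet on the far
wall raises a geometry error naming the angular coverage.

## Mass and volume

`mass = N · Δx² · (thickness + gap) · ρ`, with ρ = 1.05 g/mL (the standard
myocardial density convention; configurable) and the effective slice
spacing `thickness + gap` (default 8 + 2 mm), i.e. each imaged slice is
taken to represent its acquisition slab plus the adjacent gap so a stack
tiles the ventricle contiguously. Both are configurable per call/stack.

## Phantom generator

The phantom is an annular myocardium (defaults: endo 20 mm, epi 32 mm,
96² grid at 1 mm, 6 slices of 8 mm + 2 mm gap) with:

- remote tissue at `remote_mean` (30) with white-noise amplitude
  `remote_sd` (5 signal units);
- blood pool at 1.5 × remote mean (bright, as on inversion-recovery LGE),
  air at 0;
- lesions painted as angular/transmural sectors at
  `remote_mean + offset·remote_sd` before noise, with pattern presets:
  mid-wall septal striae (depth 0.30–0.70 of the wall), RV insertion
  (full-thickness wedge at an insertion angle), sub-epicardial
  (0.70–1.00, non-septal by default), diffuse (whole wall);
- two insertion angles (120°/240°) delimiting the septum, and a remote
  reference wedge placed diametrically opposite the septal mid-angle,
  mid-myocardial (25–75 % wall depth, 60° span, ≈ 980 voxels ≥ the 50-voxel
  floor).

**Noise model.** White Gaussian noise is added per voxel and the image is
then smoothed in-plane with a Gaussian point-spread function of
σ = 0.5 px (`psf_sigma_px`, 0 disables). This models the spatially
correlated noise of filtered MRI reconstructions and is what makes
threshold-based recovery well-posed: under strictly independent noise a
lesion painted at 6 SD and thresholded at 5 SD would lose Φ(−1) ≈ 16 % of
its interior voxels regardless of the noise amplitude, so no segmentation
could recover the painted burden to within a boundary shell. With the PSF,
the measured remote SD falls well below the lesion's contrast, interior
misses become negligible, and the residual error is confined to a
sub-voxel shell at the blurred lesion boundary — which is also how real
LGE images behave. Ground truth (lesion mask, burden percentages, LV mass)
is computed analytically from the painted voxel sets, independent of the
contour-rasterization path used by the measurement pipeline.

All randomness in one phantom flows from a single `noise_seed`; identical
specs are bit-identical. `random_phantom_spec(seed)` draws a variable
septal striae lesion (arc 60–110°, randomized depth band) plus an optional
RV-insertion lesion, providing burden variability for recovery and
reproducibility studies.

## Cohort simulator

One row per patient: age ~ N(57, 14²) (clipped 18–95), 42 % female,
LVEF ~ N(32, 12²) % (clipped 8–70), and a zero-inflated septal burden at
the 5SD threshold: zero with probability 0.45, else Gamma(shape 2,
mean 5.3 %), giving a marginal mean ± SD of ≈ 2.9 ± 3.8 % — the scale of
burden reported for NIDCM cohorts, with the zero mass matching the roughly
half of patients who show no enhancement. Burdens at 3SD and 2SD add
independent Gamma increments (means 4.0 and 4.2 %), preserving the
monotone nesting lower thresholds imply. The zero-inflated mixture is a
modelling choice; published summaries give only means ± SD.

Event times are exponential with hazard
`baseline · exp(β_pct · septal5 + β_lvef · (LVEF − 32))`, defaults
β_pct = ln(1.21) per %, β_lvef = ln(0.93) per %, baseline 0.02/yr — chosen
so a ~2-year follow-up yields roughly a 15–20 % primary-event fraction.
Censoring is administrative (uniform 0.1–4.2 yr), random loss to follow-up
(0.02/yr) and non-cardiac death (0.02/yr), all independent; non-cardiac
death is treated as censoring for the cardiac endpoints, matching how such
registries fit Cox models (no competing-risk decomposition). Composite
events are split 70 % appropriate ICD therapy / 35 % cardiac death with a
5 % overlap band receiving both, and 15 % of cardiac deaths marked sudden.
A degenerate mixture (`pos_shape=None`) yields a binary 0/1 marker for
rate-ratio recovery studies.

## Validation statistics

- **Adjudication:** primary = cardiac death ∪ appropriate ICD therapy,
  secondary = appropriate ICD therapy ∪ sudden cardiac death, each at the
  earliest qualifying time; a patient with several qualifying events counts
  once. Event times after the recorded follow-up are a validation error
  listing patient ids.
- **ROC cutoff:** Youden's J maximized over midpoints between consecutive
  distinct marker values; ties broken toward higher specificity, then the
  higher cutoff. Positivity is strict (`marker > cutoff`).
- **Annual event rates:** 100 · events / Σ person-years per group; two
  groups are compared with an exact conditional Poisson test (the published
  figures do not name their test; the exact test is the conservative
  choice at these event counts).
- **Survival:** Kaplan–Meier and the two-group log-rank test via
  `lifelines`; Cox models via `lifelines.CoxPHFitter` with Efron tie
  handling (less biased than Breslow, and the tie method is otherwise
  unspecified), Wald χ² = z², and a scaled-Schoenfeld proportional-hazards
  p-value per covariate. Constant, duplicated (|r| > 0.9999) or
  rank-deficient covariates raise a collinearity error before fitting;
  non-convergence raises an explicit fit error.
- **NRI:** category-free (continuous), since no risk categories are defined
  for this criterion. Risks are each Cox model's predicted event
  probability at a fixed horizon (default 2 years ≈ the median follow-up of
  the motivating cohort). The default baseline model is (age, LVEF), with
  the augmented model adding the septal marker. CI: standard asymptotic
  variance of the two reclassification proportions; a percentile bootstrap
  is available (`nri_bootstrap_ci`).
- **ICC:** two-way random effects, absolute agreement, single measure —
  ICC(A,1) — with the McGraw–Wong F-based CI. Zero between-subject variance
  is an explicit error (the coefficient is undefined, not zero).
- **Bland–Altman:** bias = mean difference, spread = SD of differences,
  limits = bias ± 1.96 · SD. A published agreement summary of the form
  "0.2 ± 8.0 g" is ambiguous between SD and limits of agreement, so both
  are reported; comparisons in this package use the SD of differences.

All p-values are two-sided at α = 0.05. No multiple-testing correction is
applied across model tables, matching standard practice for these analyses.

## Problem sizes used in the shipped studies

The test-suite and acceptance-script studies use 50 phantoms (96² × 6
voxels) for ground-truth recovery, 100 random 32³ stacks for the
nesting/exhaustive-scan check, simulated cohorts of n = 2000 with 100–200
replicates for Cox recovery, 1000 random instances for the ROC
brute-force comparison, and 15 phantoms × 2 automated readers (remote ROI
rotated 20° and narrowed to 50°) for the reproducibility harness. These
sizes give Monte-Carlo standard errors comfortably below the effects being
checked while keeping a full run in the tens of seconds.

## What the synthetic data does and does not establish

The generators emulate the geometry, signal statistics and hazard structure
the method operates on — not MRI physics. No inversion-recovery simulation,
no motion or surface-coil shading artefacts, no multi-scanner variability,
no contour-placement error (contours are exact by construction), and
lesions are crisp sectors rather than histologically irregular fibrosis.
Passing tests therefore establish that the implementation is faithful to
its stated rules and that the statistical machinery recovers known truth
under those rules; they do not re-establish the clinical performance of
the criterion on patients. DICOM series ingestion is out of scope (NIfTI +
JSON contours are the interchange formats), as are FWHM segmentation,
T1/ECV mapping, AHA segment models and competing-risk (Fine–Gray)
modelling.

## Known limitations

- The septal-arc rule assumes roughly convex, roughly annular slices;
  grossly non-convex contours would make the angular wedge a poor septum
  model.
- The exact Poisson rate comparison conditions on total events and can be
  conservative for very small counts.
- The analytic NRI variance ignores the sampling variability of the fitted
  Cox risks themselves; use the bootstrap CI when that matters.
- `lifelines` emits convergence warnings on near-separated data before the
  package raises its explicit error; fits that converge with warnings are
  reported as-is.
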