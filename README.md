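# septalge

Objective quantification of septal fibrosis on late gadolinium enhancement
(LGE) cardiac MRI, with the outcome-validation statistics needed to benchmark
it as a prognostic criterion in non-ischemic dilated cardiomyopathy (NIDCM).

Expert visual scoring of mid-wall septal "striae" enhancement predicts
cardiac death and appropriate ICD therapy in NIDCM, but it does not transfer
to non-expert sites. This package implements the objective alternative:
threshold-based scar segmentation restricted to an anatomically defined
septal region, reported in grams and as a percentage of LV mass, plus the
full statistical battery used to validate such a criterion against clinical
outcomes. Because no suitable public imaging/outcome dataset exists, the
package also ships first-class synthetic generators — LGE phantoms with
exact fibrosis ground truth and simulated follow-up cohorts with known
hazard structure — so every stage is testable end to end.

It is aimed at cardiac-imaging researchers prototyping quantitative LGE
criteria, and at anyone needing a reproducible reference implementation of
the STRM + septal-region workflow and its validation statistics.

## Method

**Segmentation (STRM).** Given a remote reference ROI in normal myocardium
with sample mean μ and SD σ, a myocardial voxel is hyperenhanced at
multiplier *k* iff its signal *S* satisfies *S > μ + kσ* (strict), for
*k* ∈ {2, 3, 5}. An expert-style mode thresholds on an absolute signal value
instead, optionally per slice. Full-width-at-half-maximum segmentation is
deliberately not provided: it requires an expert to point at fibrosis first.

**Septal region.** The septum is the myocardium between, and inclusive of,
the two RV insertion points, with each border extended 10 mm beyond the
point of contact; the extension is converted to an angle as arc length
along the mid-wall circumference (10/r_mid radians). Voxels are assigned by
centre-point inclusion about the epicardial centroid.

**Burden.** mass = N_voxels · Δx² · (slice thickness + gap) · ρ with
ρ = 1.05 g/mL; percentages use total LV mass as denominator for both total
and septal burden. A patient is septal-fibrosis positive when septal burden
exceeds a cutoff (validated values: 2.74 % for 5SD, 6.63 % for 3SD,
10.15 % for 2SD of LV mass, strict inequality).

**Validation statistics.** Endpoint adjudication (primary: cardiac death or
appropriate ICD therapy; secondary: appropriate ICD therapy or sudden
cardiac death; non-cardiac death censors), Youden-optimal ROC cutoffs,
sensitivity/specificity/PPV/NPV and patients missed, annual event rates per
100 patient-years with an exact Poisson comparison, Kaplan–Meier curves and
log-rank tests, Cox proportional-hazards models (Efron ties, Schoenfeld
diagnostic), category-free net reclassification improvement, ICC(A,1) with
F-based CIs, and Bland–Altman limits of agreement.

## Worked example

```python
import septalge as s

# a phantom with one mid-wall septal striae lesion, 6 remote-SDs bright
spec = s.PhantomSpec(lesion_list=(s.LesionSpec(),), noise_seed=7)
stack, contours, truth = s.generate_phantom(spec)
masks, remote, results = s.analyze_stack(stack, contours)

print(f"remote ROI: mean {remote.mean:.1f}, sd {remote.sd:.2f} ({remote.n_voxels} voxels)")
print(f"ground truth septal burden: {truth.true_septal_pct:.2f} % of LV mass")
for k, r in sorted(results.items()):
    print(f"STRM >{k:.0f}SD: septal {r.septal_mass_g:.2f} g = {r.septal_pct:.2f} % "
          f"(LV mass {r.lv_mass_g:.1f} g) -> positive at 2.74 %: "
          f"{s.classify_septal_positive(r, 2.74)}")
```

prints

```
remote ROI: mean 29.9, sd 3.31 (984 voxels)
ground truth septal burden: 9.98 % of LV mass
STRM >2SD: septal 14.42 g = 11.65 % (LV mass 123.7 g) -> positive at 2.74 %: True
STRM >3SD: septal 12.60 g = 10.18 % (LV mass 123.7 g) -> positive at 2.74 %: True
STRM >5SD: septal 12.34 g = 9.97 % (LV mass 123.7 g) -> positive at 2.74 %: True
```

The 5SD segmentation recovers the 9.98 % ground truth essentially exactly
(the measured remote SD is below the white-noise amplitude because of the
reconstruction point-spread smoothing; see `docs/methods.md`). At lower
multipliers the threshold drops, so the measured burden grows — the nesting
scar(5SD) ⊆ scar(3SD) ⊆ scar(2SD) always holds.

The same workflow is available from the shell:

```bash
septalge simulate-phantom --seed 7 --out ph/
septalge quantify --image ph/phantom.nii.gz --contours ph/contours.json --out result.json
septalge simulate-cohort --seed 1 --n-patients 2000 --out cohort.csv
septalge validate --cohort cohort.csv --cutoff 2.74 --out report.json
septalge run-all --seed 1 --out run/
```

## Conventions

Contour polygons are in millimetres in the image plane, origin at the image
corner, x rightward and y downward; voxel indices are 0-based
(slice, row, col). Cohort CSVs carry one row per patient with the columns
`patient_id, age, sex, lvef_pct, septal_pct_5sd, septal_pct_3sd,
septal_pct_2sd, followup_years, cardiac_death, appropriate_icd, scd,
noncardiac_death`.
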