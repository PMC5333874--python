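# diabetes-typology

Phenotyping likely diabetes subtypes — **likely Type 1**, **likely Type 2**
and **atypical diabetes** — from the fasting biomarkers that population
surveys actually collect: fasting plasma glucose, fasting serum insulin, and
BMI. Large surveys rarely record clinically confirmed diabetes type, and no
national adult survey measures the autoantibodies that identify Type 1
diabetes; this package classifies instead from physiology.

## How it works

Six binary indicators are derived per subject from the homeostasis model
assessment (HOMA) surrogates and body size:

* HOMA-IR = insulin × glucose(mmol/L) / 22.5 ≤ 1.7 → `low_homa_ir`
* HOMA-%β = 20 × insulin / (glucose − 3.5) ≤ 81.7 → `low_homa_beta`
* HOMA-%S = 100 / HOMA-IR ≥ 65 → `high_homa_s`
* BMI < 25 kg/m² → `low_normal_bmi`
* glucose(mg/dL) / insulin > 20 → `high_gi_ratio`
* fasting insulin < 5 μU/mL → `low_fasting_insulin`

A latent class model (Bernoulli mixture, P(**y**) = Σₖ πₖ Πⱼ ρₖⱼ^yⱼ(1−ρₖⱼ)^{1−yⱼ})
is fit by EM with multiple seeded random starts; the number of classes is
chosen by a sequential parametric bootstrap likelihood-ratio test of k vs
k−1 classes. Three-class solutions are labeled deterministically from their
profiles: insulin-sensitive/deficient → likely T1DM, insulin-resistant with
low glucose:insulin ratio → likely T2DM, the remainder → atypical DM.
Validation utilities cross-tabulate the Type-2 label against a C-peptide
gold standard (sensitivity/specificity/PPV) and compare logistic regressions
of diabetes status on classical Type-2 correlates with and without the
non-Type-2 classes removed.

Current insulin users are always excluded (exogenous insulin invalidates
every fasting-insulin surrogate), and diabetes is ascertained by
self-reported diagnosis or HbA1c ≥ 6.5%.

See `docs/methods.md` for the full model description, parameter defaults and
limitations.

## Worked example

```python
import diabetes_typology as dt

# a synthetic survey: 800 diabetics (mixed subtypes) + 400 non-diabetics
cohort = dt.gen_cohort(n_diabetic=800, n_nondiabetic=400, seed=42)

est = dt.DiabetesTypology(k=3, random_state=5).fit(cohort)
res = est.result_
print(res.exclusion_log)
print({k: round(v, 2) for k, v in res.class_percentages.items()})
print("entropy:", round(res.fit_statistics.relative_entropy, 3))

table, metrics, _ = dt.validate_against_cpeptide(res, cohort)
print({k: round(v, 1) for k, v in metrics.items()})
```

prints

```
{'not_diabetic': 400, 'insulin_use': 113, 'eligible': 687}
{'likely_T1DM': 12.08, 'likely_T2DM': 71.62, 'atypical_DM': 16.3}
entropy: 0.997
{'sensitivity': 79.8, 'specificity': 98.6, 'ppv': 99.8}
```

400 simulated non-diabetics and 113 insulin users were excluded; the
three-class fit assigns 72% of the remaining 687 diabetics to the
likely-T2DM class with near-certain posteriors (entropy 0.997), and the
Type-2 label agrees closely with the C-peptide gold standard built into the
generator.

The same pipeline is available from the shell:

```bash
dtm simulate --n 800 --seed 42 --out-dir work
dtm run work/cohort.csv --k 3 --seed 5 --out-dir work
dtm validate work/cohort.csv --k 3 --seed 5
```

Real CSVs with different column names or units are bound via a YAML config
(`--config`): column mapping, glucose unit (mg/dL or mmol/L), waist unit,
cut-point overrides, and thresholds.

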