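# Methods

## The typology model

The package classifies adults with diabetes into three phenotypic groups —
likely Type 1, likely Type 2 and atypical diabetes — using only measurements
routinely available in population surveys: fasting plasma glucose, fasting
serum insulin, and body size. No autoantibody panel or clinical chart review
is required.

### From biomarkers to indicators

Six binary indicators are derived per subject. Three come from the
homeostasis model assessment (glucose G in mmol/L, insulin I in μU/mL):

* HOMA-IR = I·G / 22.5 (insulin resistance),
* HOMA-%β = 20·I / (G − 3.5) (β-cell insulin output, percent),
* HOMA-%S = 100 / HOMA-IR (insulin sensitivity, percent),

plus BMI = weight/height², the glucose:insulin ratio G:I (glucose here in
mg/dL), and raw fasting insulin. Cut points (all configurable through
`CutPoints`):

| indicator | rule | rationale |
|---|---|---|
| `low_homa_ir` | HOMA-IR ≤ 1.7 | little insulin resistance |
| `low_homa_beta` | HOMA-%β ≤ 81.7 | impaired insulin production |
| `high_homa_s` | HOMA-%S ≥ 65 | preserved insulin sensitivity |
| `low_normal_bmi` | BMI < 25 | lean/normal body habitus |
| `high_gi_ratio` | G:I > 20 | glucose high relative to insulin |
| `low_fasting_insulin` | insulin < 5 μU/mL | insulin deficiency |

Boundary conventions: the three HOMA cuts are inclusive, the BMI, G:I and
insulin cuts strict. A HOMA-%β formula occasionally circulates with insulin
omitted from the numerator; that variant is degenerate (it approaches 2000%
for all diabetic glucose values and can never fall below an 81.7% cut), so
this package implements the standard homeostasis-model form with insulin in
the numerator. Glucose unit conversion uses 18.0 mg/dL per mmol/L; the
0.09% difference from the exact molar-mass factor is far below the cut-point
sensitivity. Waist circumference cut points are 88.9 cm (women) / 101.6 cm
(men), the exact metric conversions of 35/40 inches; an inches flag converts
on ingest.

Current insulin users are excluded before any indicator is computed:
exogenous insulin invalidates every fasting-insulin-based surrogate.
Subjects missing any of glucose, insulin or BMI are excluded
(complete-case), counted and logged; an indicator vector is never partially
emitted. HOMA-%β is undefined at glucose ≤ 3.5 mmol/L; such records are
flagged and excluded (they are essentially never diabetic anyway).

### The latent class model

For subject *i* with indicator vector **y**ᵢ ∈ {0,1}⁶ and K classes,

P(**y**ᵢ) = Σₖ πₖ Πⱼ ρₖⱼ^yᵢⱼ (1−ρₖⱼ)^(1−yᵢⱼ),

i.e. a Bernoulli mixture with local independence within class. Maximum
likelihood is obtained by EM. Numerical choices:

* Likelihood and posteriors use log-space accumulation with log-sum-exp.
* Data are collapsed to unique response patterns (≤ 2⁶ = 64) with counts, so
  EM cost is independent of n.
* ρ is clamped to [10⁻⁶, 1−10⁻⁶]; perfectly separating indicators would
  otherwise drive the log-likelihood to −∞ for held-out patterns.
* Starts: π ~ Dirichlet(1,…,1), ρ ~ Uniform(0.2, 0.8), from a seeded
  generator; 50 starts by default. Starts follow the common two-stage
  scheme: a short burst (80 iterations) for every start, full convergence
  (tolerance 10⁻⁸ relative log-likelihood change, cap 1000 iterations) for
  the best tenth. If no promoted start converges, the remaining starts are
  continued before declaring non-convergence.
* A start whose class responsibility collapses below 10⁻¹² is discarded with
  a warning rather than redrawn, so the number of attempts is bounded and
  results are bit-reproducible under one seed.
* Fits are deterministic: identical data, K, start count and seed give
  bit-identical results.

### Choosing the number of classes

Entropy, AIC and BIC are reported per fitted K. Relative entropy is
E = 1 − Σᵢₖ(−pᵢₖ ln pᵢₖ)/(n ln K) ∈ [0,1]; 1 means every subject is assigned
with certainty.

The k-vs-(k−1) decision uses a parametric bootstrap likelihood-ratio test:
the observed statistic 2(ℓₖ − ℓₖ₋₁) is compared with its null distribution
from B = 99 datasets simulated under the fitted (k−1)-class model and refit
at both orders; p = (1 + #{LRT_b ≥ LRT_obs}) / (B_eff + 1). This replaces
the analytic Vuong–Lo–Mendell–Rubin approximations (implemented only inside
commercial software) with a fully specified procedure testing the same
hypothesis — the one deliberate methodological substitution in this package.
Sequential testing starts at k = 2 and stops at the first non-significant
test (α = 0.05), so exactly the 3-vs-2 and 4-vs-3 comparisons are made when
three classes are selected with k_max = 4.

Two details keep the test well-behaved. The k-class fit always includes a
deterministic start built by splitting the (k−1) solution's largest class
(weight halved, profile perturbed ±0.05), so the nested likelihood ordering
holds in practice and LRT_obs ≥ 0. Replicate refits — which are fits to
*null* data, where the k-class likelihood has a flat ridge — use a looser
tolerance (10⁻⁶) and a higher iteration cap (2000); replicates that still
fail to converge are dropped with a warning and B_effective is reported.

### Labeling classes

For K = 3 a deterministic profile rule replaces labeling by inspection:
the class with the highest ρ(high HOMA-%S) is insulin-sensitive and
insulin-deficient → **likely T1DM**; of the two remaining, the class with
the lowest ρ(high G:I) has high insulin relative to glucose → **likely
T2DM**; the remainder is **atypical DM**. Exact ties break toward the
larger class and are logged. The rule reproduces the printed class order of
all four published three-class solutions bundled as fixtures. For K ≠ 3
classes are reported unlabeled.

Diabetes ascertainment combines self-reported diagnosis with HbA1c ≥ 6.5%
(the standard diagnostic criterion; the threshold is configurable because
no single value is canonical across surveys). Subjects with neither field
are indeterminate and excluded with a named reason.

## Validation components

* **C-peptide gold standard.** Fasting C-peptide < 0.26 nmol/L is treated
  as "low" (insulin-deficient). The 0.26 default is an implementation
  choice — reference intervals for fasting C-peptide vary by assay — and is
  prominently configurable. The 2×2 of predicted likely-T2DM against
  normal/high vs low C-peptide yields sensitivity, specificity and PPV,
  computed in exact rational arithmetic; a zero denominator reports the
  metric as undefined, never 0.
* **Correlate regressions.** Logistic models (maximum likelihood via
  statsmodels, Wald 95% CIs) of diabetes status on demographics and the six
  dichotomous Type-2 correlates are fit twice: all diabetics vs
  non-diabetics, and model-defined likely-T2DM vs non-diabetics with the
  other two classes removed. McFadden's pseudo-R² (1 − ℓ/ℓ₀) is used; the
  flavor is stated in the output because several pseudo-R²s exist. The two
  models have different outcome vectors and n, so the −2LL "improvement" is
  reported descriptively, not as a nested test. Waist circumference may
  enter continuously (per cm) or as the binary high-waist indicator; both
  appear in applied practice and both are supported.

## The synthetic cohort generator

Real survey microdata cannot be redistributed, so the package tests itself
on two synthetic levels.

**Indicator level** (`gen_indicators`): class ~ Categorical(π), indicators
independent Bernoulli(ρ) given class — exactly the model's own assumption.
The four published three-class solutions (class sizes and class-conditional
percentages, stored verbatim to two decimals; π is derived from the integer
class sizes, not the rounded percentage row) serve as generating truth.
Class composition can be fixed to the printed integer sizes, which is what
the reproduction checks do.

**Biomarker level** (`gen_cohort`): per latent type, glucose and insulin are
drawn from a correlated bivariate log-normal and BMI from a normal, with
default settings chosen so that dichotomization reproduces each type's
indicator profile to within ±10 percentage points:

| type | glucose median (mg/dL), σ(log) | insulin median (μU/mL), σ(log) | log-corr | BMI mean ± sd |
|---|---|---|---|---|
| T1-like | 124, 0.25 | 2.7, 0.5 | −0.5 | 24.8 ± 3.0 |
| T2-like | 140, 0.20 | 16, 0.5 | 0.0 | 31.0 ± 4.0 |
| atypical | 220, 0.20 | 6.5, 0.4 | +0.5 | 28.0 ± 3.5 |
| non-diabetic | 95, 0.10 | 8, 0.5 | +0.3 | 27.5 ± 5.0 |

The negative log-correlation in the T1-like class keeps HOMA-IR uniformly
low while preserving realistic spread in the G:I ratio (the two indicators
pull the joint distribution in opposite directions). These settings are
invented configuration — deliberately *not* estimates of any survey's joint
distribution. HbA1c is 6.5 + Exponential(0.9) for diabetics (mean 7.4%,
matching typical diabetic samples) and < 6.5 for generated non-diabetics;
70% of diabetics self-report a diagnosis; a configurable fraction
(default 15%) are flagged as insulin users to exercise the exclusion path;
C-peptide is 0.07·insulin·e^N(0,0.3) nmol/L, so insulin-deficient subjects
fall below the low cutoff with high probability; covariates (age, waist,
triglycerides, blood pressure) carry type-dependent shifts so the classical
Type-2 correlates associate with the Type-2-like class.

Because the biomarker generator induces the algebraic dependencies among
indicators (high HOMA-%S forces low HOMA-IR, etc.), it is the right level
for end-to-end pipeline tests; the independence-level generator is the right
level for checks on the fitted LCA itself, whose entropy and class shares
are properties of a locally independent model. Passing tests on these
cohorts demonstrate internal consistency of the method, not performance on
real survey data, whose indicator dependence within class, measurement
error and missingness patterns the generator does not emulate.

## Problem sizes used in the bundled checks

The reproduction checks refit at the printed sample sizes (n = 276–451, 50
EM starts); entropy and class-share checks average 20 seeded replicates;
model-order checks run the sequential bootstrap with B = 99 on all four
solutions; parameter-recovery checks use n = 5000.

## Known limitations

* On a cohort simulated from the intermediate-certainty published solution
  (the 2009–2010 column), refitting reproduces entropy in the 0.81–0.90
  range with a mean near 0.87 rather than the printed 0.817. Two effects
  push upward: the simulator's local independence (the model-implied
  population entropy of the printed parameters is 0.850, vs 0.817 observed
  on real, dependent data), and in-sample refit bias at n = 394 — on some
  replicates the maximum-likelihood solution is a genuinely different,
  higher-certainty partition (verified by likelihood comparison against
  truth-initialized EM). The discrepancy is reported as computed.
* The bootstrap LRT is not the analytic VLMR/LMR test; p-values agree in
  decision but not in value.
* Class labels are "likely" types. The model is undefined for
  normoglycemic or pre-diabetic subjects and says nothing about gestational
  or monogenic diabetes beyond lumping non-conforming profiles into the
  atypical class.
* No survey weights: estimates describe the analyzed sample, not the
  underlying population.
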