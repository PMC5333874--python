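"""Synthetic cohorts for every pipeline stage.

Two levels of simulation:

1. :func:`gen_indicators` draws binary indicator matrices directly from a
   latent class model (class ~ Categorical(π), indicators independent
   Bernoulli(ρ) given class) — exactly the LCA's own data-generating
   assumption.  The four published three-class solutions are available as
   fixtures via :func:`reference_solution`.

2. :func:`gen_cohort` draws biomarker-level subject records — fasting
   glucose/insulin (correlated log-normals), BMI (normal), HbA1c, C-peptide
   and Type-2 correlate covariates — per latent diabetes type, so that
   dichotomizing the biomarkers approximately reproduces each type's
   indicator profile.  Unlike level 1, the derived indicators are
   algebraically coupled (e.g. high HOMA-%S forces low HOMA-IR), as in real
   cohorts.  All distribution settings are configuration, not estimates of
   any survey's joint distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .indicators import INDICATOR_COLUMNS

__all__ = [
    "SAMPLE_IDS",
    "ReferenceSolution",
    "GeneratorParams",
    "ClassBiomarkers",
    "DEFAULT_BIOMARKERS",
    "reference_solution",
    "gen_indicators",
    "simulate_reference",
    "gen_cohort",
]

# Published three-class solutions: class sizes and class-conditional
# percentages (class × indicator, in INDICATOR_COLUMNS order), stored
# verbatim as printed (two decimals).
_REFERENCE_SOLUTIONS = {
    "nhanes_2003_04": {
        "sizes": (32, 202, 42),
        "rho_pct": [
            [100.00, 96.90, 99.10, 46.40, 81.40, 90.70],
            [1.50, 49.00, 0.00, 10.40, 0.00, 0.00],
            [4.10, 100.00, 0.00, 19.20, 100.00, 20.90],
        ],
        "pct": (11.59, 73.19, 15.22),
        "entropy": 0.998,
    },
    "nhanes_2005_06": {
        "sizes": (44, 182, 44),
        "rho_pct": [
            [100.00, 88.70, 90.20, 36.10, 72.10, 74.40],
            [1.50, 51.50, 0.00, 6.10, 0.00, 0.00],
            [0.00, 100.00, 0.00, 29.50, 100.00, 13.60],
        ],
        "pct": (16.30, 67.41, 16.30),
        "entropy": 0.996,
    },
    "nhanes_2009_10": {
        "sizes": (37, 289, 68),
        "rho_pct": [
            [100.00, 78.50, 94.20, 40.20, 70.00, 70.00],
            [0.00, 24.20, 0.00, 2.80, 0.00, 0.00],
            [2.50, 100.00, 0.00, 21.30, 43.00, 3.60],
        ],
        "pct": (9.39, 73.35, 17.26),
        "entropy": 0.817,
    },
    "cardia_2010": {
        "sizes": (44, 363, 44),
        "rho_pct": [
            [100.00, 72.40, 97.10, 29.80, 45.20, 63.20],
            [1.90, 36.70, 0.00, 5.20, 0.00, 0.00],
            [0.00, 100.00, 0.00, 15.90, 100.00, 11.40],
        ],
        "pct": (9.76, 80.49, 9.76),
        "entropy": 0.998,
    },
}

SAMPLE_IDS = tuple(_REFERENCE_SOLUTIONS)


@dataclass(frozen=True)
class ReferenceSolution:
    """One published three-class solution, stored as printed."""

    sample_id: str
    sizes: tuple
    rho_pct: np.ndarray       # 3 × 6, percentages as printed
    pct: tuple                # printed class-percentage row
    entropy: float            # printed relative entropy

    @property
    def total(self) -> int:
        return int(sum(self.sizes))

    @property
    def pi(self) -> np.ndarray:
        """Mixing proportions derived from the class sizes (not the rounded
        percentage row)."""
        sizes = np.asarray(self.sizes, dtype=float)
        return sizes / sizes.sum()

    @property
    def rho(self) -> np.ndarray:
        """Class-conditional probabilities (percentages / 100)."""
        return self.rho_pct / 100.0


def reference_solution(sample_id: str) -> ReferenceSolution:
    """The published class sizes and conditional probabilities for one sample."""
    try:
        d = _REFERENCE_SOLUTIONS[sample_id]
    except KeyError:
        raise KeyError(
            f"unknown sample_id {sample_id!r}; choose from {SAMPLE_IDS}"
        ) from None
    return ReferenceSolution(
        sample_id=sample_id,
        sizes=tuple(d["sizes"]),
        rho_pct=np.asarray(d["rho_pct"], dtype=float),
        pct=tuple(d["pct"]),
        entropy=d["entropy"],
    )


def gen_indicators(pi, rho, n, seed=None, exact_sizes=None):
    """Binary indicator matrix from a latent class model.

    class ~ Categorical(π), indicator_j | class ~ Bernoulli(ρ_class,j)
    independently.  If ``exact_sizes`` is given (sequence summing to n), the
    class composition is fixed to those counts instead of drawn from π.
    Returns ``(X, labels)`` with X an n×J int array.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    pi = np.asarray(pi, dtype=float)
    rho = np.atleast_2d(np.asarray(rho, dtype=float))
    if np.any(rho < 0) or np.any(rho > 1):
        raise ValueError("rho entries must lie in [0, 1]")
    if exact_sizes is not None:
        sizes = np.asarray(exact_sizes, dtype=int)
        if sizes.sum() != n:
            raise ValueError("exact_sizes must sum to n")
        labels = np.repeat(np.arange(len(sizes)), sizes)
    else:
        if abs(pi.sum() - 1.0) > 1e-9:
            raise ValueError("pi must sum to 1")
        labels = rng.choice(len(pi), size=n, p=pi)
    X = (rng.random((n, rho.shape[1])) < rho[labels]).astype(np.int8)
    return X, labels


def simulate_reference(sample_id: str, seed=None, exact_sizes: bool = True):
    """Simulate an indicator cohort from a published solution.

    With ``exact_sizes`` (default) the class composition equals the printed
    class counts, so n equals the printed diabetic total.  Returns
    ``(X, labels, fixture)``.
    """
    fx = reference_solution(sample_id)
    sizes = fx.sizes if exact_sizes else None
    X, labels = gen_indicators(fx.pi, fx.rho, fx.total, seed=seed, exact_sizes=sizes)
    return X, labels, fx


# -- biomarker-level generator ----------------------------------------------

@dataclass(frozen=True)
class ClassBiomarkers:
    """Per-type biomarker distributions.

    Glucose (mg/dL) and insulin (μU/mL) are a correlated bivariate log-normal
    (location = log median, scale on the log, correlation on the logs); BMI is
    normal.  Defaults are chosen so the derived binary indicators approximate
    a published class profile; they are configuration, not survey estimates.
    """

    glucose_median: float
    glucose_sigma: float
    insulin_median: float
    insulin_sigma: float
    log_corr: float
    bmi_mean: float
    bmi_sd: float
    age_mean: float = 55.0
    waist_shift: float = 0.0      # added to sex-specific baseline waist, cm
    trig_median: float = 120.0
    dbp_shift: float = 0.0
    sbp_shift: float = 0.0

    def draw(self, n, rng):
        cov = np.array(
            [
                [self.glucose_sigma**2, self.log_corr * self.glucose_sigma * self.insulin_sigma],
                [self.log_corr * self.glucose_sigma * self.insulin_sigma, self.insulin_sigma**2],
            ]
        )
        mean = np.log([self.glucose_median, self.insulin_median])
        logs = rng.multivariate_normal(mean, cov, size=n)
        glucose, insulin = np.exp(logs[:, 0]), np.exp(logs[:, 1])
        bmi = np.clip(rng.normal(self.bmi_mean, self.bmi_sd, size=n), 15.0, None)
        return glucose, insulin, bmi


# Insulin-deficient (Type-1-like): low insulin, moderately high glucose,
# lean-to-normal BMI.  Negative log-correlation keeps HOMA-IR uniformly low
# while leaving realistic spread in the glucose:insulin ratio.
_T1 = ClassBiomarkers(
    glucose_median=124.0, glucose_sigma=0.25,
    insulin_median=2.7, insulin_sigma=0.5, log_corr=-0.5,
    bmi_mean=24.8, bmi_sd=3.0,
    age_mean=48.0, waist_shift=-6.0, trig_median=110.0,
)
# Insulin-resistant (Type-2-like): high insulin, high glucose, high BMI,
# elevated Type-2 correlates.
_T2 = ClassBiomarkers(
    glucose_median=140.0, glucose_sigma=0.2,
    insulin_median=16.0, insulin_sigma=0.5, log_corr=0.0,
    bmi_mean=31.0, bmi_sd=4.0,
    age_mean=62.0, waist_shift=12.0, trig_median=190.0,
    dbp_shift=5.0, sbp_shift=10.0,
)
# Atypical: severe hyperglycemia with mid-range insulin — β-cell failure
# without the Type-1 insulin deficit.
_ATYP = ClassBiomarkers(
    glucose_median=220.0, glucose_sigma=0.2,
    insulin_median=6.5, insulin_sigma=0.4, log_corr=0.5,
    bmi_mean=28.0, bmi_sd=3.5,
    age_mean=58.0, waist_shift=4.0, trig_median=140.0,
)
_NONDM = ClassBiomarkers(
    glucose_median=95.0, glucose_sigma=0.1,
    insulin_median=8.0, insulin_sigma=0.5, log_corr=0.3,
    bmi_mean=27.5, bmi_sd=5.0,
    age_mean=45.0, trig_median=110.0,
)

DEFAULT_BIOMARKERS = {"t1dm": _T1, "t2dm": _T2, "atypical": _ATYP, "nondiabetic": _NONDM}

#: Default latent-type mix among diabetics (class sizes 32/202/42 over 276).
DEFAULT_CLASS_PROBS = {"t1dm": 32 / 276, "t2dm": 202 / 276, "atypical": 42 / 276}

C_PEPTIDE_COEF = 0.07     # nmol/L per μU/mL of fasting insulin (median)
C_PEPTIDE_SIGMA = 0.3


@dataclass(frozen=True)
class GeneratorParams:
    """Settings for the biomarker-level cohort generator."""

    n_diabetic: int = 1000
    n_nondiabetic: int = 0
    class_probs: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_PROBS))
    biomarkers: dict = field(default_factory=lambda: dict(DEFAULT_BIOMARKERS))
    insulin_user_fraction: float = 0.15
    self_report_rate: float = 0.7
    seed: int | None = None

    def replace(self, **kw) -> "GeneratorParams":
        return replace(self, **kw)


def _covariates(types, settings, rng):
    n = len(types)
    male = rng.random(n) < 0.5
    sex = np.where(male, "male", "female")
    age = np.empty(n)
    waist = np.empty(n)
    trig = np.empty(n)
    dbp = np.empty(n)
    sbp = np.empty(n)
    for t in np.unique(types):
        m = types == t
        s = settings[t]
        k = m.sum()
        age[m] = np.clip(rng.normal(s.age_mean, 12.0, k), 20, 85)
        waist[m] = np.where(male[m], 100.0, 92.0) + s.waist_shift + rng.normal(0, 10.0, k)
        trig[m] = np.exp(rng.normal(np.log(s.trig_median), 0.45, k))
        dbp[m] = rng.normal(75.0 + s.dbp_shift, 10.0, k)
        sbp[m] = rng.normal(122.0 + s.sbp_shift, 15.0, k)
    race = rng.choice(
        ["nh_white", "nh_black", "hispanic", "other"], size=n, p=[0.45, 0.22, 0.28, 0.05]
    )
    return {
        "sex": sex,
        "age": np.round(age, 1),
        "race": race,
        "married": rng.random(n) < 0.55,
        "education": rng.choice(
            ["hs_or_less", "some_college", "college"], size=n, p=[0.45, 0.3, 0.25]
        ),
        "waist_circumference": np.round(waist, 1),
        "triglycerides": np.round(trig, 1),
        "total_cholesterol": np.round(rng.normal(200.0, 35.0, n), 1),
        "dbp": np.round(dbp, 1),
        "sbp": np.round(sbp, 1),
    }


def gen_cohort(params: GeneratorParams | None = None, **kwargs) -> pd.DataFrame:
    """Biomarker-level synthetic cohort with ground-truth type labels.

    Returns a DataFrame in the pipeline's canonical schema: ``subject_id``,
    ``fasting_glucose`` (mg/dL), ``fasting_insulin`` (μU/mL), ``bmi``,
    ``hba1c``, ``self_report_dm``, ``insulin_use``, ``c_peptide`` (nmol/L),
    covariates, and ``true_class`` ∈ {t1dm, t2dm, atypical, nondiabetic}.

    All diabetics have HbA1c ≥ 6.5%; a ``self_report_rate`` fraction also
    self-report a diagnosis.  An ``insulin_user_fraction`` of diabetics is
    flagged as current insulin users (for exclusion-path testing).  C-peptide
    scales with endogenous insulin, so insulin-deficient subjects fall below
    a low cutoff with high probability.
    """
    if params is None:
        params = GeneratorParams(**kwargs)
    elif kwargs:
        params = params.replace(**kwargs)
    rng = np.random.default_rng(params.seed)

    labels = list(params.class_probs)
    probs = np.asarray([params.class_probs[k] for k in labels], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("class_probs must sum to 1")
    types = np.array(
        [labels[i] for i in rng.choice(len(labels), size=params.n_diabetic, p=probs)]
    )
    if params.n_nondiabetic:
        types = np.concatenate([types, np.repeat("nondiabetic", params.n_nondiabetic)])
    n = len(types)

    glucose = np.empty(n)
    insulin = np.empty(n)
    bmi = np.empty(n)
    for t in np.unique(types):
        m = types == t
        s = params.biomarkers[t]
        if not isinstance(s, ClassBiomarkers):
            raise ValueError(f"biomarker settings for {t!r} must be ClassBiomarkers")
        if s.glucose_sigma < 0 or s.insulin_sigma < 0 or s.bmi_sd < 0:
            raise ValueError("distribution scales must be non-negative")
        glucose[m], insulin[m], bmi[m] = s.draw(int(m.sum()), rng)

    diabetic = types != "nondiabetic"
    hba1c = np.where(
        diabetic,
        6.5 + rng.exponential(0.9, n),
        np.clip(rng.normal(5.4, 0.3, n), 4.0, 6.4),
    )
    self_report = diabetic & (rng.random(n) < params.self_report_rate)
    insulin_use = diabetic & (rng.random(n) < params.insulin_user_fraction)
    c_peptide = C_PEPTIDE_COEF * insulin * np.exp(rng.normal(0, C_PEPTIDE_SIGMA, n))

    df = pd.DataFrame(
        {
            "subject_id": [f"S{i:06d}" for i in range(n)],
            "fasting_glucose": np.round(glucose, 1),
            "fasting_insulin": np.round(insulin, 2),
            "bmi": np.round(bmi, 1),
            "hba1c": np.round(hba1c, 2),
            "self_report_dm": self_report,
            "insulin_use": insulin_use,
            "c_peptide": np.round(c_peptide, 3),
            **_covariates(types, params.biomarkers, rng),
            "true_class": types,
        }
    )
    return df
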