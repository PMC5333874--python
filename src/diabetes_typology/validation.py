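"""Validation of typology labels: C-peptide gold standard and regression checks.

Fasting C-peptide tracks endogenous insulin secretion: low in insulin-deficient
(Type-1-like) diabetes, normal/high when secretion is preserved (Type-2-like).
Cross-tabulating predicted *likely T2DM* against C-peptide low vs normal/high
gives sensitivity, specificity and positive predictive value for the Type-2
label.

The regression checks fit logistic models of diabetes status on the classical
Type-2 correlates twice — once with every diabetic as a case, once keeping
only the model-defined likely-T2DM cases — and report the gain in McFadden
pseudo-R² and the −2 log-likelihoods.  The two models use different outcome
vectors (different n), so the comparison is descriptive, not a nested test.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "ConfusionTable",
    "RegressionComparison",
    "SeparationError",
    "cpeptide_gold",
    "crosstab_metrics",
    "validate_against_cpeptide",
    "logistic_fit",
    "compare_outcome_definitions",
    "DEFAULT_CORRELATE_FORMULA_COLUMNS",
]


class SeparationError(RuntimeError):
    """A covariate perfectly separates the outcome; ML estimates diverge."""


@dataclass(frozen=True)
class ConfusionTable:
    """2×2 counts: prediction = likely_T2DM vs other, gold = C-peptide
    normal/high vs low."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def cpeptide_gold(c_peptide, cutoff: float = 0.26):
    """Classify C-peptide (nmol/L) as ``"low"`` or ``"normal_high"``.

    Values at the cutoff count as normal/high.  The default cutoff of
    0.26 nmol/L is a configurable implementation choice for "low" fasting
    C-peptide, not a published constant of the typology itself.
    """
    arr = np.asarray(c_peptide, dtype=float)
    out = np.where(arr < cutoff, "low", "normal_high")
    out = np.where(np.isnan(arr), None, out)
    return out.item() if arr.ndim == 0 else out


def crosstab_metrics(table: ConfusionTable) -> dict:
    """Sensitivity, specificity and PPV (in percent) by exact rational
    arithmetic; a zero denominator yields None, never 0."""
    def pct(num, den):
        return float(Fraction(num, den) * 100) if den > 0 else None

    return {
        "sensitivity": pct(table.tp, table.tp + table.fn),
        "specificity": pct(table.tn, table.tn + table.fp),
        "ppv": pct(table.tp, table.tp + table.fp),
    }


def validate_against_cpeptide(result, cohort: pd.DataFrame, cutoff: float = 0.26):
    """Build the 2×2 of predicted likely-T2DM against C-peptide and score it.

    Uses only eligible subjects with a C-peptide measurement; returns
    ``(ConfusionTable, metrics, n_missing_cpeptide)``.  Raises if no subject
    carries C-peptide.
    """
    assign = result.assignments
    cp = pd.to_numeric(
        cohort.loc[assign.index, "c_peptide"], errors="coerce"
    ) if "c_peptide" in cohort.columns else pd.Series(np.nan, index=assign.index)
    have = cp.notna()
    n_missing = int((~have).sum())
    if not have.any():
        raise ValueError("no C-peptide data among eligible subjects; validation skipped")
    pred_t2 = (assign.loc[have, "label"] == "likely_T2DM").to_numpy()
    gold_pos = (cp[have] >= cutoff).to_numpy()      # normal/high = positive
    table = ConfusionTable(
        tp=int(np.sum(pred_t2 & gold_pos)),
        fp=int(np.sum(pred_t2 & ~gold_pos)),
        fn=int(np.sum(~pred_t2 & gold_pos)),
        tn=int(np.sum(~pred_t2 & ~gold_pos)),
    )
    return table, crosstab_metrics(table), n_missing


@dataclass
class RegressionComparison:
    """One fitted logistic model with the fit statistics used for comparison."""

    outcome: str
    n: int
    coefficients: pd.Series
    odds_ratios: pd.DataFrame       # OR, ci_low, ci_high per term
    loglik: float
    loglik_null: float
    pseudo_r2: float                # McFadden: 1 − ll / ll_null
    df_model: int


def _check_separation(y: np.ndarray, X: pd.DataFrame):
    for col in X.columns:
        x = X[col].to_numpy(dtype=float)
        if x.std() == 0:
            continue
        if x[y == 1].size and x[y == 0].size:
            if x[y == 1].min() > x[y == 0].max() or x[y == 1].max() < x[y == 0].min():
                raise SeparationError(f"covariate {col!r} perfectly separates the outcome")


def logistic_fit(y, X, outcome_name: str = "outcome", add_intercept: bool = True) -> RegressionComparison:
    """Maximum-likelihood logistic regression with Wald 95% CIs.

    ``X`` is a numeric DataFrame (dummy-code categoricals upstream).  Raises
    :class:`SeparationError` naming the covariate under perfect separation.
    """
    y = np.asarray(y, dtype=float)
    X = pd.DataFrame(X).astype(float)
    _check_separation(y, X)
    design = sm.add_constant(X, has_constant="add") if add_intercept else X
    model = sm.Logit(y, design)
    res = model.fit(disp=0, maxiter=200)
    ci = res.conf_int()
    or_table = pd.DataFrame(
        {
            "OR": np.exp(res.params),
            "ci_low": np.exp(ci[0]),
            "ci_high": np.exp(ci[1]),
        }
    )
    return RegressionComparison(
        outcome=outcome_name,
        n=len(y),
        coefficients=res.params,
        odds_ratios=or_table,
        loglik=float(res.llf),
        loglik_null=float(res.llnull),
        pseudo_r2=float(1.0 - res.llf / res.llnull) if res.llnull != 0 else 0.0,
        df_model=int(res.df_model),
    )


#: Covariates of the standard correlate regression, as canonical columns.
DEFAULT_CORRELATE_FORMULA_COLUMNS = [
    "race", "sex", "age", "married", "education", "waist_circumference",
    "total_cholesterol", "triglycerides", "dbp", "sbp", "fasting_glucose",
    "fasting_insulin",
]


def build_correlate_design(cohort: pd.DataFrame, waist_continuous: bool = True) -> pd.DataFrame:
    """Design matrix of demographics + dichotomized Type-2 correlates.

    Waist circumference can enter continuously (gender-adjusted, default) or
    as the binary high-waist indicator; both forms are supported because the
    dichotomous definition and a continuous per-cm odds ratio both appear in
    applied use of these correlates.
    """
    from .indicators import derive_correlates

    corr = derive_correlates(cohort)
    design = pd.DataFrame(index=cohort.index)
    race = cohort.get("race")
    if race is not None:
        for level in ("hispanic", "nh_black", "other"):
            design[f"race_{level}"] = (race == level).astype(float)
    sex = cohort.get("sex")
    if sex is not None:
        design["male"] = sex.map(lambda s: s in (1, "1", "male", "M", "m", True)).astype(float)
    if "age" in cohort.columns:
        design["age"] = pd.to_numeric(cohort["age"], errors="coerce")
    if "married" in cohort.columns:
        design["married"] = cohort["married"].fillna(False).astype(bool).astype(float)
    edu = cohort.get("education")
    if edu is not None:
        design["edu_hs_or_less"] = (edu == "hs_or_less").astype(float)
        design["edu_some_college"] = (edu == "some_college").astype(float)
    if waist_continuous and "waist_circumference" in cohort.columns:
        design["waist_circumference"] = pd.to_numeric(
            cohort["waist_circumference"], errors="coerce"
        )
    else:
        design["high_waist"] = corr["high_waist"]
    for col in ("severe_ir", "high_trig", "high_chol", "high_dbp", "high_sbp"):
        design[col] = corr[col]
    return design


def compare_outcome_definitions(
    cohort: pd.DataFrame,
    result,
    covariates: pd.DataFrame | None = None,
    waist_continuous: bool = True,
) -> dict:
    """Fit the correlate regression under both outcome definitions.

    Model A: all ascertained diabetics vs non-diabetics.  Model B: only the
    model-defined likely-T2DM cases vs non-diabetics (likely-T1DM and
    atypical cases removed).  Reports both pseudo-R², their difference, both
    −2 log-likelihoods, the −2LL improvement and model df.  The models are
    fit on different outcome vectors (different n); the improvement line is a
    descriptive comparison, not a nested-model test.
    """
    from .pipeline import ascertain_diabetes

    status = ascertain_diabetes(cohort)
    dm = status["is_diabetic"].to_numpy()
    if covariates is None:
        covariates = build_correlate_design(cohort, waist_continuous=waist_continuous)
    covariates = covariates.dropna(axis=1, how="all")

    t2_index = result.assignments.index[result.assignments["label"] == "likely_T2DM"]
    is_t2 = pd.Series(False, index=cohort.index)
    is_t2.loc[t2_index] = True
    non_t2_dm = dm & ~is_t2.to_numpy()

    keep_a = covariates.notna().all(axis=1).to_numpy()
    fit_all = logistic_fit(dm[keep_a], covariates[keep_a], outcome_name="all_DM")

    keep_b = keep_a & ~non_t2_dm                       # drop classes 1 and 3
    fit_t2 = logistic_fit(
        is_t2.to_numpy()[keep_b], covariates[keep_b], outcome_name="DTM_T2DM"
    )
    return {
        "pseudo_r2_all_dm": fit_all.pseudo_r2,
        "pseudo_r2_t2dm": fit_t2.pseudo_r2,
        "r2_increase_best_class": fit_t2.pseudo_r2 - fit_all.pseudo_r2,
        "neg2ll_all_dm": -2.0 * fit_all.loglik,
        "neg2ll_t2dm": -2.0 * fit_t2.loglik,
        "improvement_neg2ll": -2.0 * fit_all.loglik - (-2.0 * fit_t2.loglik),
        "df_model": fit_all.df_model,
        "n_all_dm": fit_all.n,
        "n_t2dm": fit_t2.n,
        "pseudo_r2_flavor": "mcfadden",
        "models": {"all_DM": fit_all, "DTM_T2DM": fit_t2},
    }
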