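"""End-to-end diabetes typology: ascertain, exclude, dichotomize, fit, label.

The full procedure on a person-level cohort table:

1. Ascertain diabetes from self-reported diagnosis or HbA1c ≥ threshold.
2. Exclude current insulin users (exogenous insulin invalidates the fasting
   HOMA surrogates) and records with incomplete indicator components.
3. Derive the six binary indicators and fit the latent class model.
4. For a three-class solution, label classes by their profiles:
   the class with the highest P(high HOMA-%S) is insulin-sensitive and
   insulin-deficient → *likely T1DM*; of the remaining two, the class with
   the lowest P(high G:I ratio) is insulin-resistant with high insulin
   relative to glucose → *likely T2DM*; the residual class is *atypical DM*.

Exposed both as functions and as the :class:`DiabetesTypology` estimator.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import lca, model_selection
from .config import AnalysisConfig
from .indicators import INDICATOR_COLUMNS, CORRELATE_COLUMNS, derive_correlates, derive_indicators
from .lca import LCAFit, LCAModel

__all__ = [
    "CLASS_LABELS",
    "PipelineError",
    "LabelingError",
    "TypologyResult",
    "ascertain_diabetes",
    "apply_exclusions",
    "label_classes",
    "run_dtm",
    "cohort_summary",
    "DiabetesTypology",
]

logger = logging.getLogger("diabetes_typology")

CLASS_LABELS = ("likely_T1DM", "likely_T2DM", "atypical_DM")

_HIGH_S = INDICATOR_COLUMNS.index("high_homa_s")      # column 2
_HIGH_GI = INDICATOR_COLUMNS.index("high_gi_ratio")   # column 4


class PipelineError(RuntimeError):
    pass


class LabelingError(ValueError):
    """Raised when profile-based labeling is requested for K ≠ 3."""


def ascertain_diabetes(cohort: pd.DataFrame, hba1c_threshold: float = 6.5) -> pd.DataFrame:
    """Per-subject diabetes status and how it was ascertained.

    A subject is diabetic if they self-report a diagnosis or their HbA1c is
    at or above the threshold (default 6.5%, the standard diagnostic
    criterion).  Subjects with both fields missing are indeterminate
    (``ascertainment = "none"``) and not counted as diabetic.
    """
    sr = cohort["self_report_dm"] if "self_report_dm" in cohort.columns else pd.Series(
        pd.NA, index=cohort.index
    )
    sr_known = sr.notna()
    sr_true = sr.notna() & (sr == True)  # noqa: E712 — nullable booleans
    a1c = pd.to_numeric(cohort.get("hba1c"), errors="coerce") if "hba1c" in cohort.columns \
        else pd.Series(np.nan, index=cohort.index)
    a1c_high = a1c >= hba1c_threshold

    how = np.select(
        [
            sr_true & a1c_high,
            sr_true,
            a1c_high,
        ],
        ["both", "self_report", "hba1c"],
        default="none",
    )
    indeterminate = ~sr_known & a1c.isna()
    how = np.where(indeterminate, "none", how)
    return pd.DataFrame(
        {
            "is_diabetic": (sr_true | a1c_high) & ~indeterminate,
            "ascertainment": how,
            "indeterminate": indeterminate,
        },
        index=cohort.index,
    )


def apply_exclusions(
    cohort: pd.DataFrame,
    config: AnalysisConfig | None = None,
):
    """Eligible diabetic subset and exclusion log.

    Eligible ⇔ diabetic ∧ not currently using insulin ∧ all six indicator
    components computable.  Returns ``(eligible_df, indicators_df, log)``
    where ``indicators_df`` holds the six binary columns for eligible rows
    and ``log`` counts exclusions by reason.
    """
    config = config or AnalysisConfig()
    status = ascertain_diabetes(cohort, config.hba1c_threshold)
    if "insulin_use" in cohort.columns:
        col = cohort["insulin_use"]
        insulin_use = col.notna() & (col == True)  # noqa: E712 — nullable booleans
    else:
        insulin_use = pd.Series(False, index=cohort.index)
    indicators = derive_indicators(cohort, config.cut_points)
    complete = indicators.notna().all(axis=1)

    reason = pd.Series("", index=cohort.index, dtype=object)
    reason[~status["is_diabetic"]] = "not_diabetic"
    reason[status["indeterminate"]] = "indeterminate_dm_status"
    mask_dm = status["is_diabetic"]
    reason[mask_dm & insulin_use] = "insulin_use"
    reason[mask_dm & ~insulin_use & ~complete] = "incomplete_indicators"

    eligible = mask_dm & ~insulin_use & complete
    log = reason[~eligible].value_counts().to_dict()
    log["eligible"] = int(eligible.sum())
    if eligible.sum() == 0:
        raise PipelineError(f"no eligible diabetic records after exclusions: {log}")
    logger.info("eligibility: %s", log)
    return cohort.loc[eligible], indicators.loc[eligible].astype(int), log


def _pick(candidates, score, pi, prefer_high=True):
    """Index among candidates optimizing score; exact ties go to larger class."""
    score = np.asarray(score, dtype=float)
    best = score.max() if prefer_high else score.min()
    tied = [c for c, s in zip(candidates, score) if s == best]
    if len(tied) > 1:
        logger.info("labeling tie among classes %s broken by class size", tied)
        return max(tied, key=lambda c: pi[c])
    return tied[0]


def label_classes(model: LCAModel) -> dict:
    """Deterministic profile-based labels for a three-class model.

    likely_T1DM = class with maximal ρ(high HOMA-%S); among the remaining
    two, likely_T2DM = class with minimal ρ(high G:I ratio); atypical_DM is
    the class left over.  Exact ties are broken toward the larger class.
    """
    if model.n_classes != 3:
        raise LabelingError(
            f"profile labeling defined only for K=3 (got K={model.n_classes})"
        )
    classes = list(range(3))
    t1 = _pick(classes, model.rho[:, _HIGH_S], model.pi, prefer_high=True)
    rest = [c for c in classes if c != t1]
    t2 = _pick(rest, [-model.rho[c, _HIGH_GI] for c in rest], model.pi, prefer_high=True)
    (atyp,) = [c for c in rest if c != t2]
    return {t1: "likely_T1DM", t2: "likely_T2DM", atyp: "atypical_DM"}


@dataclass
class TypologyResult:
    """Everything the end-to-end run produces."""

    fit: LCAFit
    label_map: dict | None                 # class index -> label (None if K != 3)
    assignments: pd.DataFrame              # subject_id, class, label, max posterior
    class_sizes: dict                      # label -> modal count
    class_percentages: dict                # label -> % of eligible diabetics
    exclusion_log: dict
    fit_statistics: model_selection.FitStatistics
    selection: model_selection.ClassCountDecision | None = None


def run_dtm(cohort: pd.DataFrame, config: AnalysisConfig | None = None) -> TypologyResult:
    """The full typology pipeline on a canonical-schema cohort DataFrame.

    The class count is ``config.k`` if fixed, otherwise chosen by sequential
    bootstrap likelihood-ratio testing up to ``config.k_max``.  Deterministic
    given ``config.seed``.
    """
    config = config or AnalysisConfig()
    eligible, indicators, log = apply_exclusions(cohort, config)
    X = indicators[INDICATOR_COLUMNS].to_numpy()

    selection = None
    if config.k is not None:
        K = config.k
    else:
        selection = model_selection.select_k(
            X, k_max=config.k_max, alpha=config.alpha, B=config.bootstrap_reps,
            seed=config.seed, n_starts=config.n_starts,
            tol=config.tol, max_iter=config.max_iter,
        )
        K = selection.selected_K
        logger.info("selected K=%d", K)

    fit_res = lca.fit(
        X, K=K, n_starts=config.n_starts, seed=config.seed,
        tol=config.tol, max_iter=config.max_iter,
    )
    stats = model_selection.information_criteria(fit_res, n=len(X))

    label_map = None
    if K == 3:
        label_map = label_classes(fit_res.model)
        labels = np.array([label_map[c] for c in fit_res.modal_class])
    else:
        warnings.warn(f"K={K}: classes reported unlabeled")
        labels = np.array([f"class_{c + 1}" for c in fit_res.modal_class])

    subject_id = (
        eligible["subject_id"]
        if "subject_id" in eligible.columns
        else pd.Series(eligible.index, index=eligible.index)
    )
    assignments = pd.DataFrame(
        {
            "subject_id": subject_id.to_numpy(),
            "modal_class": fit_res.modal_class + 1,
            "label": labels,
            "max_posterior": fit_res.posteriors.max(axis=1),
        },
        index=eligible.index,
    )
    for k in range(K):
        assignments[f"posterior_{k + 1}"] = fit_res.posteriors[:, k]

    counts = pd.Series(labels).value_counts().to_dict()
    n_elig = len(labels)
    ordered = CLASS_LABELS if label_map else sorted(counts)
    sizes = {lab: int(counts.get(lab, 0)) for lab in ordered}
    pcts = {lab: 100.0 * v / n_elig for lab, v in sizes.items()}
    return TypologyResult(
        fit=fit_res,
        label_map=label_map,
        assignments=assignments,
        class_sizes=sizes,
        class_percentages=pcts,
        exclusion_log=log,
        fit_statistics=stats,
        selection=selection,
    )


def cohort_summary(cohort: pd.DataFrame, config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Prevalence of the six indicators and six correlates, full sample vs
    diabetics, plus means of the continuous covariates."""
    config = config or AnalysisConfig()
    status = ascertain_diabetes(cohort, config.hba1c_threshold)
    indicators = derive_indicators(cohort, config.cut_points)
    correlates = derive_correlates(cohort)
    binary = pd.concat([indicators, correlates], axis=1)

    rows = {}
    dm = status["is_diabetic"]
    for col in INDICATOR_COLUMNS + CORRELATE_COLUMNS:
        rows[f"pct_{col}"] = [
            100.0 * binary[col].mean(),
            100.0 * binary.loc[dm, col].mean() if dm.any() else np.nan,
        ]
    for col in ("hba1c", "waist_circumference", "age", "bmi"):
        if col in cohort.columns:
            vals = pd.to_numeric(cohort[col], errors="coerce")
            rows[f"mean_{col}"] = [
                vals.mean(), vals[dm].mean() if dm.any() else np.nan
            ]
    rows["n"] = [len(cohort), int(dm.sum())]
    return pd.DataFrame(rows, index=["full_sample", "diabetics"]).T


class DiabetesTypology:
    """scikit-learn style estimator wrapping the end-to-end typology.

    ``fit`` takes a canonical-schema cohort DataFrame; fitted attributes
    expose the latent class model, label map and per-subject assignments.
    ``predict`` labels new data (a cohort DataFrame or a ready n×6 binary
    indicator matrix) under the fitted model.
    """

    def __init__(
        self,
        k: int | None = 3,
        k_max: int = 4,
        n_starts: int = 50,
        bootstrap_reps: int = 99,
        alpha: float = 0.05,
        hba1c_threshold: float = 6.5,
        random_state: int | None = None,
    ):
        self.k = k
        self.k_max = k_max
        self.n_starts = n_starts
        self.bootstrap_reps = bootstrap_reps
        self.alpha = alpha
        self.hba1c_threshold = hba1c_threshold
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            "k": self.k, "k_max": self.k_max, "n_starts": self.n_starts,
            "bootstrap_reps": self.bootstrap_reps, "alpha": self.alpha,
            "hba1c_threshold": self.hba1c_threshold,
            "random_state": self.random_state,
        }

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _config(self) -> AnalysisConfig:
        return AnalysisConfig(
            k=self.k, k_max=self.k_max, n_starts=self.n_starts,
            bootstrap_reps=self.bootstrap_reps, alpha=self.alpha,
            hba1c_threshold=self.hba1c_threshold, seed=self.random_state,
        )

    def fit(self, X: pd.DataFrame, y=None):
        self.result_ = run_dtm(X, self._config())
        self.model_ = self.result_.fit.model
        self.label_map_ = self.result_.label_map
        self.labels_ = self.result_.assignments["label"].to_numpy()
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted")
        if isinstance(X, pd.DataFrame) and not set(INDICATOR_COLUMNS).issubset(X.columns):
            ind = derive_indicators(X)
            mat = ind[INDICATOR_COLUMNS].to_numpy()
        else:
            mat = pd.DataFrame(X)[INDICATOR_COLUMNS].to_numpy() \
                if isinstance(X, pd.DataFrame) else np.asarray(X)
        classes = lca.posterior(self.model_, mat.astype(int)).argmax(axis=1)
        if self.label_map_:
            return np.array([self.label_map_[c] for c in classes])
        return classes
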