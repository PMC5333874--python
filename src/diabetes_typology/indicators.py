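"""HOMA surrogates, glucose:insulin ratio, BMI, and their dichotomization.

The typology model works on six binary indicators derived from three fasting
biomarkers (plasma glucose, serum insulin) and body size:

* ``low_homa_ir``       — HOMA-IR ≤ 1.7 (little insulin resistance)
* ``low_homa_beta``     — HOMA-%β ≤ 81.7 (impaired β-cell insulin output)
* ``high_homa_s``       — HOMA-%S ≥ 65 (preserved insulin sensitivity)
* ``low_normal_bmi``    — BMI < 25 kg/m²
* ``high_gi_ratio``     — glucose:insulin ratio > 20 (insulin-deficient pattern)
* ``low_fasting_insulin`` — fasting insulin < 5 μU/mL

HOMA-IR and HOMA-%S use glucose in mmol/L; the G:I ratio uses mg/dL.  All cut
points are configurable through :class:`CutPoints`.

A second set of six binary covariates (:func:`derive_correlates`) encodes the
classical Type-2-diabetes correlates: gender-adjusted high waist circumference,
severe insulin resistance (HOMA-IR ≥ 5), high triglycerides, high total
cholesterol, and high diastolic / systolic blood pressure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "INDICATOR_COLUMNS",
    "CORRELATE_COLUMNS",
    "GLUCOSE_MGDL_PER_MMOL",
    "CutPoints",
    "InvalidMeasurementError",
    "UndefinedIndexError",
    "MissingIndicatorError",
    "glucose_to_mmol",
    "homa_ir",
    "homa_beta",
    "homa_s",
    "bmi",
    "gi_ratio",
    "dichotomize",
    "derive_indicators",
    "derive_correlates",
    "IndicatorBinarizer",
]

#: Fixed order of the six model indicators, used everywhere downstream.
INDICATOR_COLUMNS = [
    "low_homa_ir",
    "low_homa_beta",
    "high_homa_s",
    "low_normal_bmi",
    "high_gi_ratio",
    "low_fasting_insulin",
]

#: Fixed order of the six Type-2 correlate covariates.
CORRELATE_COLUMNS = [
    "high_waist",
    "severe_ir",
    "high_trig",
    "high_chol",
    "high_dbp",
    "high_sbp",
]

#: Conversion constant: mg/dL of glucose per mmol/L.
GLUCOSE_MGDL_PER_MMOL = 18.0

# Gender-adjusted waist cut points, exact conversions of 35 in / 40 in.
WAIST_CUT_FEMALE_CM = 88.9
WAIST_CUT_MALE_CM = 101.6
CM_PER_INCH = 2.54


class InvalidMeasurementError(ValueError):
    """A biomarker value is outside its physically valid range."""


class UndefinedIndexError(ValueError):
    """A HOMA index is undefined at this input (e.g. glucose ≤ 3.5 mmol/L)."""


class MissingIndicatorError(ValueError):
    """An indicator cannot be computed because a component is missing."""


@dataclass(frozen=True)
class CutPoints:
    """Dichotomization thresholds for the six indicators.

    Boundary conventions follow the model's definitions: HOMA-IR, HOMA-%β and
    HOMA-%S cuts are inclusive; BMI < 25, G:I > 20 and insulin < 5 are strict.
    """

    homa_ir_max: float = 1.7          # low_homa_ir: HOMA-IR <= cut
    homa_beta_max: float = 81.7       # low_homa_beta: HOMA-%β <= cut
    homa_s_min: float = 65.0          # high_homa_s: HOMA-%S >= cut
    bmi_max: float = 25.0             # low_normal_bmi: BMI < cut
    gi_min: float = 20.0              # high_gi_ratio: G:I > cut
    insulin_max: float = 5.0          # low_fasting_insulin: insulin < cut

    def to_dict(self) -> dict:
        return asdict(self)

    def replace(self, **kwargs) -> "CutPoints":
        return replace(self, **kwargs)


def _require_positive(name: str, value):
    arr = np.asarray(value, dtype=float)
    if np.any(arr[~np.isnan(arr)] <= 0):
        raise InvalidMeasurementError(f"{name} must be > 0")


def glucose_to_mmol(glucose_mg_dl):
    """Convert fasting glucose from mg/dL to mmol/L (divide by 18)."""
    arr = np.asarray(glucose_mg_dl, dtype=float)
    if np.any(arr[~np.isnan(arr)] < 0):
        raise InvalidMeasurementError("fasting glucose must be >= 0 mg/dL")
    out = arr / GLUCOSE_MGDL_PER_MMOL
    return out.item() if np.isscalar(glucose_mg_dl) else out


def homa_ir(glucose_mmol, insulin):
    """HOMA-IR = insulin (μU/mL) × glucose (mmol/L) / 22.5.

    Higher values indicate more insulin resistance; ≥ 5 is severe.
    """
    _require_positive("glucose (mmol/L)", glucose_mmol)
    _require_positive("insulin (μU/mL)", insulin)
    out = np.asarray(insulin, dtype=float) * np.asarray(glucose_mmol, dtype=float) / 22.5
    return out.item() if out.ndim == 0 else out

def homa_beta(glucose_mmol, insulin):
    """HOMA-%β = 20 × insulin / (glucose − 3.5), in percent.

    Estimates pancreatic β-cell insulin production; undefined for glucose
    ≤ 3.5 mmol/L (non-diabetic range where the homeostasis model breaks down).
    """
    _require_positive("insulin (μU/mL)", insulin)
    g = np.asarray(glucose_mmol, dtype=float)
    if np.any(g[~np.isnan(g)] <= 3.5):
        raise UndefinedIndexError(
            "HOMA-%β undefined for glucose <= 3.5 mmol/L"
        )
    out = 20.0 * np.asarray(insulin, dtype=float) / (g - 3.5)
    return out.item() if out.ndim == 0 else out


def homa_s(glucose_mmol, insulin):
    """HOMA-%S = 100 / HOMA-IR, in percent (insulin sensitivity)."""
    out = 100.0 / np.asarray(homa_ir(glucose_mmol, insulin), dtype=float)
    return out.item() if out.ndim == 0 else out


def bmi(weight_kg, height_m):
    """Body mass index, weight (kg) / height (m)²."""
    _require_positive("weight (kg)", weight_kg)
    _require_positive("height (m)", height_m)
    out = np.asarray(weight_kg, dtype=float) / np.asarray(height_m, dtype=float) ** 2
    return out.item() if out.ndim == 0 else out


def gi_ratio(glucose_mgdl, insulin):
    """Glucose:insulin ratio, glucose (mg/dL) / insulin (μU/mL)."""
    _require_positive("glucose (mg/dL)", glucose_mgdl)
    _require_positive("insulin (μU/mL)", insulin)
    out = np.asarray(glucose_mgdl, dtype=float) / np.asarray(insulin, dtype=float)
    return out.item() if out.ndim == 0 else out


def dichotomize(glucose_mgdl, insulin, bmi_value, cut_points: CutPoints | None = None):
    """Six binary indicators for one subject (scalars) or arrays of subjects.

    Parameters use glucose in mg/dL (converted internally to mmol/L where the
    HOMA formulas require it).  Returns a dict (scalars) or DataFrame (arrays)
    in the :data:`INDICATOR_COLUMNS` order.

    Raises :class:`MissingIndicatorError` naming the missing component when a
    scalar input is NaN or None.
    """
    cuts = cut_points or CutPoints()
    scalar = np.isscalar(glucose_mgdl) or glucose_mgdl is None
    g = np.atleast_1d(np.asarray(glucose_mgdl, dtype=float))
    i = np.atleast_1d(np.asarray(insulin, dtype=float))
    b = np.atleast_1d(np.asarray(bmi_value, dtype=float))
    if scalar:
        for name, v in [("fasting_glucose", g), ("fasting_insulin", i), ("bmi", b)]:
            if np.isnan(v).any():
                raise MissingIndicatorError(f"cannot dichotomize: {name} is missing")
    g_mmol = g / GLUCOSE_MGDL_PER_MMOL
    with np.errstate(invalid="ignore", divide="ignore"):
        ir = i * g_mmol / 22.5
        beta = np.where(g_mmol > 3.5, 20.0 * i / (g_mmol - 3.5), np.nan)
        sens = 100.0 / ir
        gi = g / i
    if scalar and g_mmol[0] <= 3.5:
        raise UndefinedIndexError("HOMA-%β undefined for glucose <= 3.5 mmol/L")
    out = {
        "low_homa_ir": ir <= cuts.homa_ir_max,
        "low_homa_beta": beta <= cuts.homa_beta_max,
        "high_homa_s": sens >= cuts.homa_s_min,
        "low_normal_bmi": b < cuts.bmi_max,
        "high_gi_ratio": gi > cuts.gi_min,
        "low_fasting_insulin": i < cuts.insulin_max,
    }
    if scalar:
        return {k: int(v[0]) for k, v in out.items()}
    df = pd.DataFrame({k: v.astype(float) for k, v in out.items()})
    # any missing/invalid component invalidates the whole indicator vector
    bad = np.isnan(g) | np.isnan(i) | np.isnan(b) | (g_mmol <= 3.5) | (g <= 0) | (i <= 0) | (b <= 0)
    df[bad] = np.nan
    return df[INDICATOR_COLUMNS]


def derive_indicators(cohort: pd.DataFrame, cut_points: CutPoints | None = None) -> pd.DataFrame:
    """Indicator matrix for a cohort DataFrame in canonical schema.

    Expects columns ``fasting_glucose`` (mg/dL), ``fasting_insulin`` (μU/mL)
    and either ``bmi`` or both ``height`` (m) and ``weight`` (kg).  Rows with
    any missing component yield NaN across all six indicator columns and an
    ``exclusion_reason`` of ``incomplete_indicators``.
    """
    g = pd.to_numeric(cohort.get("fasting_glucose"), errors="coerce")
    i = pd.to_numeric(cohort.get("fasting_insulin"), errors="coerce")
    if "bmi" in cohort.columns:
        b = pd.to_numeric(cohort["bmi"], errors="coerce")
    else:
        b = pd.Series(np.nan, index=cohort.index)
    if {"height", "weight"}.issubset(cohort.columns):
        h = pd.to_numeric(cohort["height"], errors="coerce")
        w = pd.to_numeric(cohort["weight"], errors="coerce")
        with np.errstate(invalid="ignore", divide="ignore"):
            b = b.fillna(w / h**2)
    out = dichotomize(g.to_numpy(), i.to_numpy(), b.to_numpy(), cut_points)
    out.index = cohort.index
    return out


def derive_correlates(cohort: pd.DataFrame, waist_in_inches: bool = False) -> pd.DataFrame:
    """Six binary Type-2-diabetes correlates from the covariate columns.

    Missing covariates produce NaN in the corresponding correlate column
    (never silently 0).  ``sex`` is expected as ``"male"``/``"female"`` (or
    1/0); waist circumference in cm unless ``waist_in_inches``.
    """
    idx = cohort.index
    out = pd.DataFrame(index=idx)

    def num(col):
        if col in cohort.columns:
            return pd.to_numeric(cohort[col], errors="coerce")
        return pd.Series(np.nan, index=idx)

    waist = num("waist_circumference")
    if waist_in_inches:
        waist = waist * CM_PER_INCH
    sex = cohort.get("sex")
    if sex is not None:
        male = sex.map(lambda s: s in (1, "1", "male", "M", "m", True))
        cut = np.where(male, WAIST_CUT_MALE_CM, WAIST_CUT_FEMALE_CM)
        out["high_waist"] = _binary_or_nan(waist >= cut, waist)
    else:
        out["high_waist"] = np.nan

    ir = num("fasting_insulin") * (num("fasting_glucose") / GLUCOSE_MGDL_PER_MMOL) / 22.5
    out["severe_ir"] = _binary_or_nan(ir >= 5.0, ir)
    trig = num("triglycerides")
    out["high_trig"] = _binary_or_nan(trig >= 200.0, trig)
    chol = num("total_cholesterol")
    out["high_chol"] = _binary_or_nan(chol >= 200.0, chol)
    dbp = num("dbp")
    out["high_dbp"] = _binary_or_nan(dbp >= 90.0, dbp)
    sbp = num("sbp")
    out["high_sbp"] = _binary_or_nan(sbp >= 140.0, sbp)
    return out[CORRELATE_COLUMNS]


def _binary_or_nan(condition, values) -> pd.Series:
    if values is None:
        return pd.Series(np.nan)
    res = pd.Series(np.where(pd.isna(values), np.nan, condition.astype(float)))
    res.index = values.index
    return res


class IndicatorBinarizer:
    """Stateless transformer: biomarker DataFrame → six binary indicators.

    scikit-learn compatible (``fit``/``transform``/``get_params``); ``fit`` is
    a no-op since the cut points are fixed configuration, not learned.
    """

    def __init__(self, cut_points: CutPoints | None = None):
        self.cut_points = cut_points

    def fit(self, X: pd.DataFrame, y=None):
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return derive_indicators(X, self.cut_points)

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(X).transform(X)

    def get_params(self, deep: bool = True) -> dict:
        return {"cut_points": self.cut_points}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self
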