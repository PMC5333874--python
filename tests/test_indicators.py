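"""Unit and property tests for the HOMA surrogates and dichotomization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from diabetes_typology.indicators import (
    INDICATOR_COLUMNS,
    CutPoints,
    InvalidMeasurementError,
    MissingIndicatorError,
    UndefinedIndexError,
    bmi,
    derive_correlates,
    derive_indicators,
    dichotomize,
    gi_ratio,
    glucose_to_mmol,
    homa_beta,
    homa_ir,
    homa_s,
    IndicatorBinarizer,
)


@pytest.mark.parametrize(
    "func, args, expected",
    [
        (glucose_to_mmol, (126,), 7.0),
        (glucose_to_mmol, (0,), 0.0),
        (glucose_to_mmol, (90,), 5.0),
        (homa_ir, (22.5, 1.0), 1.0),
        (homa_ir, (7.0, 10.0), 70 / 22.5),
        (homa_ir, (5.0, 4.0), 20 / 22.5),
        (homa_beta, (7.0, 10.0), 200 / 3.5),
        (homa_beta, (4.5, 1.0), 20.0),
        (homa_s, (22.5, 1.0), 100.0),
        (homa_s, (7.0, 10.0), 100 / (70 / 22.5)),
        (bmi, (70, 1.75), 70 / 3.0625),
        (bmi, (25, 1.0), 25.0),
        (bmi, (100, 2.0), 25.0),
        (gi_ratio, (126, 10), 12.6),
        (gi_ratio, (100, 5), 20.0),
        (gi_ratio, (200, 4), 50.0),
    ],
)
def test_index_formulas(func, args, expected):
    assert func(*args) == pytest.approx(expected, rel=1e-9)


@pytest.mark.parametrize(
    "func, args, exc",
    [
        (glucose_to_mmol, (-1,), InvalidMeasurementError),
        (homa_ir, (0.0, 5.0), InvalidMeasurementError),
        (homa_ir, (5.0, -2.0), InvalidMeasurementError),
        (homa_beta, (3.5, 10.0), UndefinedIndexError),
        (homa_beta, (3.0, 10.0), UndefinedIndexError),
        (bmi, (70, 0.0), InvalidMeasurementError),
        (gi_ratio, (100, 0.0), InvalidMeasurementError),
    ],
)
def test_invalid_measurements_raise(func, args, exc):
    with pytest.raises(exc):
        func(*args)


@settings(max_examples=200, deadline=None)
@given(
    g=st.floats(min_value=0.5, max_value=40.0),
    i=st.floats(min_value=0.1, max_value=300.0),
)
def test_sensitivity_resistance_reciprocal_identity(g, i):
    """HOMA-%S × HOMA-IR = 100 algebraically for any valid glucose/insulin."""
    assert homa_s(g, i) * homa_ir(g, i) == pytest.approx(100.0, rel=1e-9)


@pytest.mark.parametrize(
    "glucose, insulin, bmi_v, expected",
    [
        # insulin-resistant profile: only low beta-cell output flags
        (126, 10, 30, (0, 1, 0, 0, 0, 0)),
        # insulin-deficient profile: all six indicators flag
        (180, 3, 22, (1, 1, 1, 1, 1, 1)),
    ],
)
def test_dichotomize_profiles(glucose, insulin, bmi_v, expected):
    vec = dichotomize(glucose, insulin, bmi_v)
    assert tuple(vec[c] for c in INDICATOR_COLUMNS) == expected


def test_dichotomize_boundary_conventions():
    """Insulin exactly 5 and BMI exactly 25 sit outside the 'low' categories;
    HOMA-IR exactly 1.7 and G:I exactly 20 sit on the inclusive/exclusive
    sides respectively."""
    vec = dichotomize(126, 5, 25)
    assert vec["low_fasting_insulin"] == 0
    assert vec["low_normal_bmi"] == 0
    # HOMA-IR == 1.7 exactly: glucose 85.0 mg/dL -> 4.7222 mmol; pick insulin
    ins = 1.7 * 22.5 / (85.0 / 18.0)
    vec = dichotomize(85.0, ins, 30)
    assert vec["low_homa_ir"] == 1          # inclusive cut
    vec = dichotomize(100, 5.0, 30)
    assert vec["high_gi_ratio"] == 0        # G:I == 20 is not "above 20"


def test_cut_point_overrides():
    cuts = CutPoints().replace(insulin_max=6.0)
    assert dichotomize(126, 5, 30, cuts)["low_fasting_insulin"] == 1


@pytest.mark.parametrize(
    "column, vary, low, high",
    [
        ("low_fasting_insulin", "insulin", 0.5, 30.0),
        ("high_gi_ratio", "insulin", 0.5, 30.0),
        ("low_homa_ir", "insulin", 0.5, 60.0),
        ("low_normal_bmi", "bmi", 16.0, 45.0),
    ],
)
def test_indicators_are_monotone_step_functions(column, vary, low, high):
    """Each indicator flips at most once as its driving measurement sweeps
    through its cut point."""
    grid = np.linspace(low, high, 400)
    vals = []
    for v in grid:
        kwargs = {"glucose": 140.0, "insulin": 8.0, "bmi_v": 30.0}
        kwargs["insulin" if vary == "insulin" else "bmi_v"] = v
        vals.append(
            dichotomize(kwargs["glucose"], kwargs["insulin"], kwargs["bmi_v"])[column]
        )
    flips = np.abs(np.diff(vals)).sum()
    assert flips <= 1


def test_missing_component_never_yields_indicators():
    with pytest.raises(MissingIndicatorError, match="fasting_insulin"):
        dichotomize(126, None, 30)
    df = pd.DataFrame(
        {"fasting_glucose": [126, np.nan], "fasting_insulin": [10, 10], "bmi": [30, 30]}
    )
    out = derive_indicators(df)
    assert out.iloc[0].notna().all()
    assert out.iloc[1].isna().all()


def test_unit_invariance_of_dichotomization():
    """Dichotomizing mg/dL data equals dichotomizing the same data converted
    to mmol/L (with mg/dL retained for the G:I ratio)."""
    rng = np.random.default_rng(0)
    g_mgdl = rng.uniform(100, 300, 50)
    ins = rng.uniform(1, 30, 50)
    b = rng.uniform(18, 40, 50)
    direct = dichotomize(g_mgdl, ins, b)
    g_mmol = g_mgdl / 18.0
    roundtrip = dichotomize(g_mmol * 18.0, ins, b)
    pd.testing.assert_frame_equal(direct, roundtrip)


def test_bmi_from_height_weight_matches_direct():
    df = pd.DataFrame(
        {
            "fasting_glucose": [180.0, 180.0],
            "fasting_insulin": [3.0, 3.0],
            "height": [1.75, 2.0],
            "weight": [70.0, 100.0],
        }
    )
    out = derive_indicators(df)
    # 70/1.75² = 22.86 < 25; 100/2² = 25 sits on the exclusive boundary
    assert out["low_normal_bmi"].tolist() == [1.0, 0.0]


def test_correlate_cut_points():
    df = pd.DataFrame(
        {
            "sex": ["male", "female", "male"],
            "waist_circumference": [101.6, 88.9, 101.5],
            "fasting_glucose": [135.0, 135.0, 135.0],   # 7.5 mmol/L
            "fasting_insulin": [15.0, 14.9, 15.0],      # HOMA-IR 5.0 / 4.97
            "triglycerides": [200.0, 199.0, np.nan],
            "total_cholesterol": [200.0, 199.0, 200.0],
            "dbp": [90.0, 89.0, 90.0],
            "sbp": [140.0, 139.0, 140.0],
        }
    )
    out = derive_correlates(df)
    assert out.loc[0].tolist() == [1, 1, 1, 1, 1, 1]
    assert out.loc[1].tolist() == [1, 0, 0, 0, 0, 0]
    assert np.isnan(out.loc[2, "high_trig"])            # missing, never 0


def test_correlates_waist_in_inches():
    df = pd.DataFrame({"sex": ["male"], "waist_circumference": [40.0]})
    out = derive_correlates(df, waist_in_inches=True)
    assert out.loc[0, "high_waist"] == 1


def test_binarizer_is_sklearn_compatible(diabetic_cohort):
    est = IndicatorBinarizer()
    out = est.fit_transform(diabetic_cohort)
    assert list(out.columns) == INDICATOR_COLUMNS
    assert est.get_params() == {"cut_points": None}
    est.set_params(cut_points=CutPoints().replace(bmi_max=30))
    out2 = est.transform(diabetic_cohort)
    assert out2["low_normal_bmi"].sum() >= out["low_normal_bmi"].sum()
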