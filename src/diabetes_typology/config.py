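"""Run configuration: column mapping, units, cut points and thresholds.

A YAML config binds CSV columns to the canonical field names, declares the
glucose unit of the file, and optionally overrides indicator cut points and
the ascertainment / validation thresholds.  Everything has a default, so an
already-canonical CSV needs no config at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import pandas as pd
import yaml

from .indicators import CutPoints

__all__ = ["AnalysisConfig", "load_config", "read_cohort"]

#: Canonical cohort column names understood by the pipeline.
CANONICAL_FIELDS = [
    "subject_id", "fasting_glucose", "fasting_insulin", "height", "weight",
    "bmi", "hba1c", "self_report_dm", "insulin_use", "c_peptide",
    "age", "sex", "race", "married", "education", "waist_circumference",
    "triglycerides", "total_cholesterol", "dbp", "sbp",
]


@dataclass
class AnalysisConfig:
    column_map: dict = field(default_factory=dict)   # canonical -> CSV column
    glucose_unit: str = "mg/dL"                      # "mg/dL" or "mmol/L"
    waist_unit: str = "cm"                           # "cm" or "in"
    cut_points: CutPoints = field(default_factory=CutPoints)
    hba1c_threshold: float = 6.5       # % — undiagnosed-diabetes ascertainment
    cpeptide_cutoff: float = 0.26      # nmol/L — "low C-peptide" gold standard
    k: int | None = None               # fix the class count; None = select
    k_max: int = 4
    n_starts: int = 50
    bootstrap_reps: int = 99
    alpha: float = 0.05
    tol: float = 1e-8
    max_iter: int = 1000
    seed: int | None = None

    def __post_init__(self):
        if self.glucose_unit not in ("mg/dL", "mmol/L"):
            raise ValueError("glucose_unit must be 'mg/dL' or 'mmol/L'")
        if self.waist_unit not in ("cm", "in"):
            raise ValueError("waist_unit must be 'cm' or 'in'")
        if isinstance(self.cut_points, dict):
            self.cut_points = CutPoints(**self.cut_points)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cut_points"] = self.cut_points.to_dict()
        return d

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def load_config(path) -> AnalysisConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    return AnalysisConfig(**doc)


_BOOL_MAP = {
    "1": True, "0": False, "true": True, "false": False, "yes": True,
    "no": False, "y": True, "n": False, True: True, False: False,
    1: True, 0: False, 1.0: True, 0.0: False,
}


def _coerce_bool(series: pd.Series) -> pd.Series:
    def conv(v):
        if pd.isna(v):
            return pd.NA
        key = v.strip().lower() if isinstance(v, str) else v
        if key in _BOOL_MAP:
            return _BOOL_MAP[key]
        raise ValueError(f"cannot interpret {v!r} as boolean")
    return series.map(conv)


def read_cohort(path, config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Read a cohort CSV into canonical schema, applying the column map and
    converting glucose to mg/dL (the internal canonical unit) and waist to cm.

    Missing values are empty fields.
    """
    config = config or AnalysisConfig()
    df = pd.read_csv(path)
    rename = {csv_col: canon for canon, csv_col in config.column_map.items()}
    missing = [c for c in rename if c not in df.columns]
    if missing:
        raise ValueError(f"mapped columns absent from CSV: {missing}")
    df = df.rename(columns=rename)
    df = df[[c for c in df.columns if c in CANONICAL_FIELDS]]
    if "fasting_glucose" in df.columns and config.glucose_unit == "mmol/L":
        df["fasting_glucose"] = pd.to_numeric(df["fasting_glucose"], errors="coerce") * 18.0
    if "waist_circumference" in df.columns and config.waist_unit == "in":
        df["waist_circumference"] = (
            pd.to_numeric(df["waist_circumference"], errors="coerce") * 2.54
        )
    for col in ("self_report_dm", "insulin_use"):
        if col in df.columns:
            df[col] = _coerce_bool(df[col])
    return df
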