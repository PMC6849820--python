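"""Observation-table reading, validation and report writing."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .effect_sizes import OBSERVATION_COLUMNS

__all__ = ["read_observations", "write_csv", "ValidationReport", "SchemaError"]


def write_csv(df: pd.DataFrame, path, index: bool = False) -> None:
    """CSV writer with round-trip-exact floats (17 significant digits).

    Stage-wise CLI runs re-read intermediate CSVs; lossless floats keep
    their outputs byte-identical to a single in-process run.
    """
    df.to_csv(path, index=index, float_format="%.17g")

log = logging.getLogger("rangemeta")

_REQUIRED = [
    "response_variable", "experiment_id", "publication_id",
    "mean_trt", "mean_ctl", "n_trt", "n_ctl",
    "climate_zone", "amount_applied", "amendment_n",
]
_NUMERIC = [
    "mean_trt", "mean_ctl", "sd_trt", "sd_ctl", "se_trt", "se_ctl",
    "n_trt", "n_ctl", "p_exact", "days_since_application",
    "amount_applied", "amendment_n", "soil_depth",
]
#: columns defining observation uniqueness (response variable + experiment +
#: measurement date + amendment type + amount applied; date and type collapse
#: to days-since-application and the amount here)
_UNIQUE_KEY = ["response_variable", "experiment_id", "days_since_application", "amount_applied"]


class SchemaError(ValueError):
    """The observation CSV is missing required columns."""


@dataclass
class ValidationReport:
    """What the reader accepted, converted, or flagged."""

    n_rows: int = 0
    converted_dates: bool = False
    duplicate_keys: list = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def read_observations(path) -> tuple[pd.DataFrame, ValidationReport]:
    """Read and validate an observation CSV.

    Missing values are empty cells.  If ``days_since_application`` is absent
    but ISO ``application_date``/``measurement_date`` columns are present,
    the day count is computed from the calendar difference.  Duplicate
    observation keys are flagged for audit, not dropped.
    """
    df = pd.read_csv(path, dtype={"p_range": str}, keep_default_na=True,
                     float_precision="round_trip")
    report = ValidationReport(n_rows=len(df))
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"observation table missing required columns: {missing}")
    if "days_since_application" not in df.columns:
        if {"application_date", "measurement_date"} <= set(df.columns):
            applied = pd.to_datetime(df["application_date"])
            measured = pd.to_datetime(df["measurement_date"])
            df["days_since_application"] = (measured - applied).dt.days.astype(float)
            report.converted_dates = True
        else:
            raise SchemaError(
                "observation table needs either days_since_application or "
                "application_date + measurement_date columns"
            )
    for col in OBSERVATION_COLUMNS:
        if col not in df.columns:
            df[col] = "" if col in ("p_range", "method_subtype") else np.nan
    for col in _NUMERIC:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["p_range"] = df["p_range"].fillna("")
    df["method_subtype"] = df["method_subtype"].fillna("")
    if len(df):
        dup = df.duplicated(subset=_UNIQUE_KEY, keep=False)
        if dup.any():
            keys = df.loc[dup, _UNIQUE_KEY].drop_duplicates().to_records(index=False)
            report.duplicate_keys = [tuple(k) for k in keys]
            msg = f"{dup.sum()} rows share {len(report.duplicate_keys)} duplicated observation keys"
            report.warnings.append(msg)
            log.warning(msg)
    else:
        report.warnings.append("observation table has no data rows")
        log.warning("observation table %s has no data rows", path)
    return df[OBSERVATION_COLUMNS + [c for c in df.columns if c not in OBSERVATION_COLUMNS]], report
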