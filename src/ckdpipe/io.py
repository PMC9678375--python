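"""Delimited-file readers and writers for the laboratory and patient tables.

All files are plain CSV with ISO-8601 dates.  The labs reader counts
malformed rows (unparseable dates, negative values, physiologically
implausible creatinine — below 20 µmol/L, the signature of mg/dL typed into
a µmol/L column, or above 4000) and logs them; more than a configurable
fraction of malformed rows is a hard failure with a row-level report.
Duplicate patient-day creatinine records are resolved by keeping the last,
mimicking laboratory report supersession.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = [
    "LABS_COLUMNS",
    "PATIENT_COLUMNS",
    "read_labs",
    "read_patients",
    "write_table",
]

log = logging.getLogger("ckdpipe")

LABS_COLUMNS = ("patient_id", "date", "creatinine_umol_l", "acr_mg_mmol")
PATIENT_COLUMNS = (
    "patient_id",
    "dob",
    "sex",
    "ethnicity",
    "diabetes",
    "hypertension",
    "ckd_coded",
    "nephrology_followup",
    "death_date",
)

CREATININE_PLAUSIBLE = (20.0, 4000.0)  # µmol/L


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


def read_labs(path, max_bad_fraction: float = 0.01) -> pd.DataFrame:
    """Read a long-format labs table; validate, deduplicate, sort.

    Returns columns (patient_id, date, creatinine_umol_l, acr_mg_mmol)
    sorted by patient then date.  An empty file yields an empty frame with a
    warning.  Malformed rows are dropped with a warning while they stay
    under ``max_bad_fraction`` of the file; above that the read fails with
    a row-level report.
    """
    df = pd.read_csv(path, dtype={"patient_id": str})
    if len(df) == 0:
        log.warning("%s: labs file is empty", path)
        return pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
            LABS_COLUMNS, (str, "datetime64[ns]", float, float))})
    _require_columns(df, LABS_COLUMNS, path)
    dates = pd.to_datetime(df["date"], format="ISO8601", errors="coerce")
    creat = pd.to_numeric(df["creatinine_umol_l"], errors="coerce")
    acr = pd.to_numeric(df["acr_mg_mmol"], errors="coerce")
    creat_given = df["creatinine_umol_l"].notna()
    acr_given = df["acr_mg_mmol"].notna()

    bad = dates.isna() | df["patient_id"].isna()
    bad |= creat_given & (
        creat.isna() | (creat < CREATININE_PLAUSIBLE[0]) | (creat > CREATININE_PLAUSIBLE[1])
    )
    bad |= acr_given & (acr.isna() | (acr < 0))
    bad |= ~creat_given & ~acr_given
    n_bad = int(bad.sum())
    if n_bad:
        report = df.loc[bad].head(20)
        frac = n_bad / len(df)
        msg = (
            f"{path}: {n_bad}/{len(df)} malformed rows "
            f"(unparseable dates/values, creatinine outside "
            f"{CREATININE_PLAUSIBLE[0]}-{CREATININE_PLAUSIBLE[1]} µmol/L — a value "
            f"like 1.0 usually means mg/dL in a µmol/L column, or negative uACR). "
            f"First offending rows:\n{report.to_string()}"
        )
        if frac > max_bad_fraction:
            raise ValueError(msg)
        log.warning(msg)
    out = pd.DataFrame(
        {
            "patient_id": df["patient_id"],
            "date": dates,
            "creatinine_umol_l": creat.where(creat_given),
            "acr_mg_mmol": acr.where(acr_given),
        }
    ).loc[~bad]
    out = out.sort_values(["patient_id", "date"], kind="mergesort")
    # lab-report supersession: last creatinine per patient-day wins
    has_creat = out["creatinine_umol_l"].notna()
    dup = has_creat & out.loc[has_creat].duplicated(["patient_id", "date"], keep="last").reindex(
        out.index, fill_value=False
    )
    has_acr = out["acr_mg_mmol"].notna()
    dup |= has_acr & out.loc[has_acr].duplicated(["patient_id", "date"], keep="last").reindex(
        out.index, fill_value=False
    )
    return out.loc[~dup].reset_index(drop=True)


_BOOL_MAP = {
    "true": True, "false": False, "1": True, "0": False, "yes": True, "no": False,
    True: True, False: False, 1: True, 0: False,
}


def _parse_bool(series: pd.Series, name: str) -> pd.Series:
    def conv(v):
        key = v.strip().lower() if isinstance(v, str) else v
        if key not in _BOOL_MAP:
            raise ValueError(f"column {name}: unrecognised boolean value {v!r}")
        return _BOOL_MAP[key]

    return series.map(conv).astype(bool)


def read_patients(path) -> pd.DataFrame:
    """Read the per-patient demographics/flags table."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    _require_columns(df, PATIENT_COLUMNS, path)
    out = pd.DataFrame(
        {
            "patient_id": df["patient_id"],
            "dob": pd.to_datetime(df["dob"], format="ISO8601"),
            "sex": df["sex"].str.lower(),
            "ethnicity": df["ethnicity"].fillna("unknown").str.lower(),
            "death_date": pd.to_datetime(df["death_date"], format="ISO8601", errors="coerce"),
        }
    )
    for col in ("diabetes", "hypertension", "ckd_coded", "nephrology_followup"):
        out[col] = _parse_bool(df[col], col)
    bad_sex = ~out["sex"].isin(["female", "male"])
    if bad_sex.any():
        raise ValueError(f"{path}: invalid sex values {out.loc[bad_sex, 'sex'].unique()!r}")
    if out["patient_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate patient_id rows")
    return out[list(PATIENT_COLUMNS)].reset_index(drop=True)


def write_table(df: pd.DataFrame, path) -> None:
    """Write a table as CSV with ISO dates; lossless round-trip for typed fields."""
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)
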