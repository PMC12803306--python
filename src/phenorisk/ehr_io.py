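"""Reading, validating and normalising the three EHR input tables.

The package consumes three comma-separated, UTF-8, headered files:

``diagnoses``
    long format, one ICD-coded encounter per row:
    ``patient_id,icd_code,icd_version,date``
``demographics``
    one row per patient: ``patient_id,birth_year,sex,race_ethnicity``
``genotypes``
    one row per patient: ``patient_id,status`` with status one of
    ``carrier``, ``noncarrier_confirmed``, ``unknown``

ICD codes are treated as opaque identifiers: they are compared only after
normalisation (uppercase, whitespace stripped, dots removed) together with
their ICD version (9 or 10). No semantic ICD knowledge is embedded and no
ICD-9 <-> ICD-10 crosswalk is attempted. Duplicate diagnosis rows are legal
and retained; collapsing to per-patient phenotype presence happens
downstream.

In memory, each table is a :class:`pandas.DataFrame` (demographics indexed
by patient id, genotypes a :class:`pandas.Series`).
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import SchemaError, ValidationError

ICD_VERSIONS = (9, 10)
GENOTYPE_STATUSES = ("carrier", "noncarrier_confirmed", "unknown")

DIAGNOSIS_COLUMNS = ["patient_id", "icd_code", "icd_version", "date"]
DEMOGRAPHICS_COLUMNS = ["patient_id", "birth_year", "sex", "race_ethnicity"]
GENOTYPE_COLUMNS = ["patient_id", "status"]

#: earliest plausible birth year accepted by validation
MIN_BIRTH_YEAR = 1880


def normalize_icd(raw_code: str, version: int) -> str:
    """Normalise an ICD code string for identifier comparison.

    Uppercases, strips surrounding whitespace and removes all ``'.'``
    characters, so that ``"I50.9"`` and ``"i509 "`` compare equal. The
    operation is idempotent.

    Parameters
    ----------
    raw_code
        The code as it appears in the source system.
    version
        ICD version, 9 or 10 (validated; the code text itself is opaque).

    Raises
    ------
    ValidationError
        If the code is empty after trimming, or the version is not 9/10.
    """
    if version not in ICD_VERSIONS:
        raise ValidationError(f"icd_version must be one of {ICD_VERSIONS}, got {version!r}")
    code = str(raw_code).strip().upper().replace(".", "")
    if not code:
        raise ValidationError(f"empty ICD code after normalisation (raw value {raw_code!r})")
    return code


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}; found {list(df.columns)}")


def _lines(mask: pd.Series) -> str:
    # +2: header is file line 1, first data row is line 2
    return ", ".join(str(i + 2) for i in np.flatnonzero(mask.to_numpy())[:20])


def read_diagnoses(path) -> pd.DataFrame:
    """Read a long-format diagnosis table.

    Every row is normalised via :func:`normalize_icd`; the row count is
    preserved (duplicate rows are legal input and kept). Malformed rows are
    reported with their file line numbers.

    Returns
    -------
    pandas.DataFrame
        Columns ``patient_id`` (str), ``icd_code`` (normalised str),
        ``icd_version`` (int), ``event_date`` (datetime64).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, DIAGNOSIS_COLUMNS, path)

    version = pd.to_numeric(df["icd_version"].str.strip(), errors="coerce")
    bad_version = ~version.isin(ICD_VERSIONS)
    if bad_version.any():
        raise ValidationError(
            f"{path}: icd_version must be 9 or 10; offending line(s) {_lines(bad_version)}"
        )

    dates = pd.to_datetime(df["date"].str.strip(), format="%Y-%m-%d", errors="coerce")
    bad_date = dates.isna()
    if bad_date.any():
        raise ValidationError(
            f"{path}: unparseable ISO date(s) (YYYY-MM-DD); offending line(s) {_lines(bad_date)}"
        )

    codes = df["icd_code"].str.strip().str.upper().str.replace(".", "", regex=False)
    empty = codes == ""
    if empty.any():
        raise ValidationError(
            f"{path}: empty icd_code after normalisation; offending line(s) {_lines(empty)}"
        )

    return pd.DataFrame(
        {
            "patient_id": df["patient_id"].str.strip(),
            "icd_code": codes,
            "icd_version": version.astype(int),
            "event_date": dates,
        }
    )


def write_diagnoses(diagnoses: pd.DataFrame, path) -> None:
    """Write a diagnosis table in the exact dialect :func:`read_diagnoses` reads."""
    out = pd.DataFrame(
        {
            "patient_id": diagnoses["patient_id"],
            "icd_code": diagnoses["icd_code"],
            "icd_version": diagnoses["icd_version"],
            "date": pd.to_datetime(diagnoses["event_date"]).dt.strftime("%Y-%m-%d"),
        }
    )
    out.to_csv(path, index=False)


def read_demographics(path) -> pd.DataFrame:
    """Read the demographics table (one row per patient).

    Returns a DataFrame indexed by ``patient_id`` with columns
    ``birth_year`` (int), ``sex`` and ``race_ethnicity`` (verbatim EHR
    strings — no label normalisation is attempted).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, DEMOGRAPHICS_COLUMNS, path)

    pid = df["patient_id"].str.strip()
    dup = pid.duplicated(keep=False)
    if dup.any():
        raise ValidationError(
            f"{path}: duplicate patient_id(s) {sorted(pid[dup].unique())[:10]}; "
            f"line(s) {_lines(dup)}"
        )

    birth_year = pd.to_numeric(df["birth_year"].str.strip(), errors="coerce")
    bad = birth_year.isna() | (birth_year != birth_year.round())
    if bad.any():
        raise ValidationError(
            f"{path}: non-integer birth_year; offending line(s) {_lines(bad)}"
        )
    birth_year = birth_year.astype(int)
    this_year = _dt.date.today().year
    out_of_range = (birth_year < MIN_BIRTH_YEAR) | (birth_year > this_year)
    if out_of_range.any():
        raise ValidationError(
            f"{path}: birth_year outside [{MIN_BIRTH_YEAR}, {this_year}]; "
            f"offending line(s) {_lines(out_of_range)}"
        )

    out = pd.DataFrame(
        {
            "birth_year": birth_year.to_numpy(),
            "sex": df["sex"].to_numpy(),
            "race_ethnicity": df["race_ethnicity"].to_numpy(),
        },
        index=pd.Index(pid, name="patient_id"),
    )
    return out


def write_demographics(demographics: pd.DataFrame, path) -> None:
    demographics.reset_index().to_csv(path, index=False)


def read_genotypes(path) -> pd.Series:
    """Read the genotype-status table into a Series indexed by patient id."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, GENOTYPE_COLUMNS, path)

    pid = df["patient_id"].str.strip()
    dup = pid.duplicated(keep=False)
    if dup.any():
        raise ValidationError(f"{path}: duplicate patient_id(s); line(s) {_lines(dup)}")

    status = df["status"].str.strip()
    bad = ~status.isin(GENOTYPE_STATUSES)
    if bad.any():
        raise ValidationError(
            f"{path}: status must be one of {GENOTYPE_STATUSES}; "
            f"offending line(s) {_lines(bad)}"
        )
    return pd.Series(status.to_numpy(), index=pd.Index(pid, name="patient_id"), name="status")


def write_genotypes(genotypes: pd.Series, path) -> None:
    genotypes.rename("status").rename_axis("patient_id").reset_index().to_csv(path, index=False)
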