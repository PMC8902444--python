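"""Reading and writing the canonical registry files.

The pipeline's input format is three delimited text files:

``patients.csv``
    patient_id, sex (F/M), birth_year, death_year, death_month
``dispensings.csv``
    patient_id, dispense_date (ISO-8601), atc_code, n_units, n_ddd, formulation
``population.csv``
    year, age (0-89), sex, drug_group, users, population
"""

from __future__ import annotations

import re
from pathlib import Path

import pandas as pd

from .simulate import PATIENT_COLUMNS, POPULATION_COLUMNS, RECORD_COLUMNS

PATIENTS_FILE = "patients.csv"
DISPENSINGS_FILE = "dispensings.csv"
POPULATION_FILE = "population.csv"

_FULL_ATC_RE = re.compile(r"^[A-Z]\d{2}[A-Z]{2}\d{2}$")


class RegistryLoadError(ValueError):
    """A registry file violates the expected schema."""


def write_registry(
    patients: pd.DataFrame,
    records: pd.DataFrame,
    population: pd.DataFrame,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write the three canonical files; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "patients": outdir / PATIENTS_FILE,
        "dispensings": outdir / DISPENSINGS_FILE,
        "population": outdir / POPULATION_FILE,
    }
    patients.to_csv(paths["patients"], index=False)
    rec = records.copy()
    if len(rec):
        rec["dispense_date"] = pd.to_datetime(rec["dispense_date"]).dt.strftime("%Y-%m-%d")
    rec.to_csv(paths["dispensings"], index=False)
    population.to_csv(paths["population"], index=False)
    return paths


def _require_columns(df: pd.DataFrame, cols: list[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise RegistryLoadError(f"{name}: missing columns {missing}")


def read_registry(indir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Load and validate (patients, dispensings, population) from a directory."""
    indir = Path(indir)
    patients = pd.read_csv(indir / PATIENTS_FILE, dtype={"patient_id": str})
    records = pd.read_csv(indir / DISPENSINGS_FILE, dtype={"patient_id": str, "atc_code": str})
    population = pd.read_csv(indir / POPULATION_FILE)

    _require_columns(patients, PATIENT_COLUMNS, PATIENTS_FILE)
    _require_columns(records, RECORD_COLUMNS, DISPENSINGS_FILE)
    _require_columns(population, POPULATION_COLUMNS, POPULATION_FILE)

    patients["death_year"] = patients["death_year"].astype("Int64")
    patients["death_month"] = patients["death_month"].astype("Int64")

    if len(records):
        try:
            records["dispense_date"] = pd.to_datetime(records["dispense_date"], format="%Y-%m-%d")
        except (ValueError, TypeError) as exc:
            raise RegistryLoadError(f"{DISPENSINGS_FILE}: unparseable dispense_date ({exc})") from exc
        bad = ~records["atc_code"].str.match(_FULL_ATC_RE)
        if bad.any():
            row = int(records.index[bad][0])
            raise RegistryLoadError(
                f"{DISPENSINGS_FILE}: row {row}: malformed ATC code {records['atc_code'].iloc[row]!r}"
            )
        if (records["n_units"] < 1).any():
            row = int(records.index[records["n_units"] < 1][0])
            raise RegistryLoadError(f"{DISPENSINGS_FILE}: row {row}: n_units must be >= 1")
    else:
        records["dispense_date"] = pd.to_datetime(records["dispense_date"])

    if len(population) and (population["users"] > population["population"]).any():
        raise RegistryLoadError(f"{POPULATION_FILE}: users exceed population in some cell")
    return patients, records, population
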