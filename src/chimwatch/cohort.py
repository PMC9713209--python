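"""Cohort data model, TSV/CSV I/O, validation and paired blood-marrow samples.

A cohort is two long-format tables:

* ``transplants`` -- one row per HSCT, with the outcome (relapse day or
  censoring day) and the covariates used by the regression models.
* ``measurements`` -- one row per chimerism result: transplant, day
  post-HSCT (day 0 = transplantation), compartment (blood/marrow),
  sorted cell lineage (CD3/CD19/CD33/CD34) and percent recipient DNA on
  the 0-100 scale.  Blood is separated into CD3/CD19/CD33 only; CD34
  occurs in marrow.  Results reported below the detection limit are
  stored as 0.0 with ``below_detection = 1``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import pearson_r

COMPARTMENTS = ("blood", "marrow")
LINEAGES = ("CD3", "CD19", "CD33", "CD34")
BLOOD_LINEAGES = ("CD3", "CD19", "CD33")
MARROW_LINEAGES = ("CD3", "CD19", "CD33", "CD34")
CONDITIONING = ("MAC", "RIC")
SOURCES = ("BM", "PB")
DONORS = ("SIB", "HAPLO", "MUD")
PEDIATRIC_AGE_LIMIT = 18.0

TRANSPLANT_COLUMNS = [
    "transplant_id", "patient_id", "age_years", "relapse_day", "censor_day",
    "conditioning", "atg", "source", "donor",
]
MEASUREMENT_COLUMNS = [
    "transplant_id", "day", "compartment", "lineage", "percent_recipient",
    "below_detection",
]


class CohortValidationError(ValueError):
    """A cohort table violates the data-model invariants."""


@dataclass
class Cohort:
    """Validated container for the two cohort tables."""

    transplants: pd.DataFrame
    measurements: pd.DataFrame

    @property
    def n_transplants(self) -> int:
        return len(self.transplants)

    def relapsed_mask(self) -> pd.Series:
        return self.transplants["relapse_day"].notna()

    def age_group(self) -> pd.Series:
        """'pediatric' (< 18 years) or 'adult' per transplant."""
        return pd.Series(
            np.where(self.transplants["age_years"] < PEDIATRIC_AGE_LIMIT,
                     "pediatric", "adult"),
            index=self.transplants.index,
        )

    def subset_age(self, group: str) -> "Cohort":
        """Restrict to one age group ('all' is a no-op copy)."""
        if group == "all":
            keep = self.transplants
        elif group in ("pediatric", "adult"):
            keep = self.transplants[self.age_group() == group]
        else:
            raise ValueError(f"unknown age group {group!r}")
        ids = set(keep["transplant_id"])
        meas = self.measurements[
            self.measurements["transplant_id"].isin(ids)
        ]
        return Cohort(keep.reset_index(drop=True), meas.reset_index(drop=True))

    def equals(self, other: "Cohort") -> bool:
        return self.transplants.equals(other.transplants) and \
            self.measurements.equals(other.measurements)


@dataclass
class PairedSample:
    """Same-transplant, same-day blood + marrow result of one lineage."""

    transplant_id: str
    day: int
    lineage: str
    blood_percent: float
    marrow_percent: float


@dataclass
class CorrelationReport:
    r: float
    n: int


def _err(messages: list[str]) -> None:
    if messages:
        raise CohortValidationError("; ".join(messages))


def validate_cohort(transplants: pd.DataFrame,
                    measurements: pd.DataFrame) -> None:
    """Raise CohortValidationError (with row numbers) on invariant
    violations.  Row numbers are 1-based data rows (header excluded)."""
    problems: list[str] = []

    for col in TRANSPLANT_COLUMNS:
        if col not in transplants.columns:
            problems.append(f"transplants: missing column {col!r}")
    for col in MEASUREMENT_COLUMNS:
        if col == "below_detection":
            continue  # optional
        if col not in measurements.columns:
            problems.append(f"measurements: missing column {col!r}")
    _err(problems)

    def flag(frame_name, mask, message, values=None):
        # report up to 10 offending rows per rule, 1-based data rows
        idx = np.flatnonzero(np.asarray(mask))
        for i in idx[:10]:
            detail = f" (got {values.iloc[i]!r})" if values is not None else ""
            problems.append(f"{frame_name} row {i + 1}: {message}{detail}")
        if idx.size > 10:
            problems.append(f"{frame_name}: ... {idx.size - 10} more rows "
                            f"with: {message}")

    t, m = transplants, measurements
    flag("transplants", t["transplant_id"].duplicated(),
         "duplicate transplant_id", t["transplant_id"])
    flag("transplants", ~t["conditioning"].isin(CONDITIONING),
         f"conditioning must be one of {CONDITIONING}", t["conditioning"])
    flag("transplants", ~t["source"].isin(SOURCES),
         f"source must be one of {SOURCES}", t["source"])
    flag("transplants", ~t["donor"].isin(DONORS),
         f"donor must be one of {DONORS}", t["donor"])
    flag("transplants", ~t["atg"].isin((0, 1)), "atg must be 0 or 1",
         t["atg"])
    flag("transplants", ~np.isfinite(t["age_years"]) | (t["age_years"] < 0),
         "invalid age_years", t["age_years"])
    flag("transplants", t["censor_day"].isna() | (t["censor_day"] < 0),
         "invalid censor_day", t["censor_day"])
    flag("transplants", t["relapse_day"].notna() & (t["relapse_day"] < 0),
         "negative relapse_day", t["relapse_day"])

    known_ids = set(t["transplant_id"])
    flag("measurements", ~m["transplant_id"].isin(known_ids),
         "orphan transplant_id", m["transplant_id"])
    flag("measurements", m["day"].isna() | (m["day"] < 0),
         "day must be >= 0", m["day"])
    flag("measurements", ~m["compartment"].isin(COMPARTMENTS),
         f"compartment must be one of {COMPARTMENTS}", m["compartment"])
    flag("measurements", ~m["lineage"].isin(LINEAGES),
         f"lineage must be one of {LINEAGES}", m["lineage"])
    flag("measurements",
         (m["lineage"] == "CD34") & (m["compartment"] != "marrow"),
         "CD34 occurs only in marrow samples")
    pct = m["percent_recipient"]
    flag("measurements", pct.isna() | (pct < 0.0) | (pct > 100.0),
         "percent_recipient out of range [0, 100]", pct)
    _err(problems)


def _coerce_transplants(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    out["transplant_id"] = out["transplant_id"].astype(str)
    out["patient_id"] = out["patient_id"].astype(str)
    out["age_years"] = pd.to_numeric(out["age_years"], errors="raise")
    out["relapse_day"] = pd.array(
        pd.to_numeric(out["relapse_day"], errors="raise"), dtype="Int64")
    out["censor_day"] = pd.to_numeric(out["censor_day"],
                                      errors="raise").astype(np.int64)
    out["atg"] = pd.to_numeric(out["atg"], errors="raise").astype(np.int64)
    for col in ("conditioning", "source", "donor"):
        out[col] = out[col].astype(str)
    return out[TRANSPLANT_COLUMNS].reset_index(drop=True)


def _coerce_measurements(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    out["transplant_id"] = out["transplant_id"].astype(str)
    out["day"] = pd.to_numeric(out["day"], errors="raise").astype(np.int64)
    out["compartment"] = out["compartment"].astype(str)
    out["lineage"] = out["lineage"].astype(str)
    out["percent_recipient"] = pd.to_numeric(out["percent_recipient"],
                                             errors="raise").astype(float)
    if "below_detection" not in out.columns:
        out["below_detection"] = 0
    out["below_detection"] = pd.to_numeric(
        out["below_detection"], errors="raise").fillna(0).astype(np.int64)
    return out[MEASUREMENT_COLUMNS].reset_index(drop=True)


def cohort_from_frames(transplants: pd.DataFrame,
                       measurements: pd.DataFrame,
                       validate: bool = True) -> Cohort:
    """Coerce dtypes and (optionally) validate; the usual constructor."""
    t = _coerce_transplants(transplants)
    m = _coerce_measurements(measurements)
    if validate:
        validate_cohort(t, m)
    return Cohort(t, m)


def load_cohort(transplants_path, measurements_path,
                delimiter: str = "\t") -> Cohort:
    """Read and validate the two cohort tables.

    Files are delimited text with a header row (TSV by default; pass
    ``delimiter=','`` for CSV).  Decimal points only.
    """
    try:
        t_raw = pd.read_csv(transplants_path, sep=delimiter, dtype=str,
                            keep_default_na=False)
        m_raw = pd.read_csv(measurements_path, sep=delimiter, dtype=str,
                            keep_default_na=False)
    except FileNotFoundError as exc:
        raise FileNotFoundError(f"cohort file not found: {exc.filename}") \
            from exc
    t_raw = t_raw.replace({"": None})
    for col in TRANSPLANT_COLUMNS:
        if col not in t_raw.columns:
            raise CohortValidationError(
                f"transplants: missing column {col!r}")
    for col in ("transplant_id", "day", "compartment", "lineage",
                "percent_recipient"):
        if col not in m_raw.columns:
            raise CohortValidationError(
                f"measurements: missing column {col!r}")
    try:
        t = _coerce_transplants(t_raw)
    except (ValueError, TypeError) as exc:
        raise CohortValidationError(
            f"transplants: type coercion failed ({exc})") from exc
    try:
        m = _coerce_measurements(m_raw)
    except (ValueError, TypeError) as exc:
        raise CohortValidationError(
            f"measurements: type coercion failed ({exc})") from exc
    validate_cohort(t, m)
    return Cohort(t, m)


def write_cohort(cohort: Cohort, transplants_path, measurements_path,
                 delimiter: str = "\t") -> None:
    """Write the two tables so that load_cohort reproduces the cohort
    field-for-field (floats use shortest round-trippable repr)."""
    cohort.transplants.to_csv(transplants_path, sep=delimiter, index=False,
                              na_rep="")
    cohort.measurements.to_csv(measurements_path, sep=delimiter, index=False,
                               na_rep="")


def paired_samples(cohort: Cohort, lineage: str) -> list[PairedSample]:
    """Same-day blood + marrow pairs of one lineage.

    A (transplant, day) contributes one pair iff it has exactly one
    blood and exactly one marrow measurement of the lineage; days with
    replicates on either side are ambiguous and excluded with a
    warning.
    """
    if lineage not in LINEAGES:
        raise ValueError(f"unknown lineage {lineage!r}")
    sub = cohort.measurements[cohort.measurements["lineage"] == lineage]
    pairs: list[PairedSample] = []
    for (tid, day), grp in sub.groupby(["transplant_id", "day"], sort=True):
        blood = grp[grp["compartment"] == "blood"]
        marrow = grp[grp["compartment"] == "marrow"]
        if len(blood) == 0 or len(marrow) == 0:
            continue
        if len(blood) > 1 or len(marrow) > 1:
            warnings.warn(
                f"replicate same-day {lineage} measurements for "
                f"{tid} day {day}; pair excluded as ambiguous",
                stacklevel=2,
            )
            continue
        pairs.append(PairedSample(
            transplant_id=str(tid),
            day=int(day),
            lineage=lineage,
            blood_percent=float(blood["percent_recipient"].iloc[0]),
            marrow_percent=float(marrow["percent_recipient"].iloc[0]),
        ))
    return pairs


def paired_correlation(pairs: list[PairedSample]) -> CorrelationReport:
    """Pearson correlation of blood vs marrow percent over paired samples."""
    blood = [p.blood_percent for p in pairs]
    marrow = [p.marrow_percent for p in pairs]
    return CorrelationReport(r=pearson_r(blood, marrow), n=len(pairs))
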