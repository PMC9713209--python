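"""Landmark filtration and the %max statistic.

To ask whether a *single* elevated chimerism value predicts relapse
with time left to intervene, measurements are filtered to a landmark
window before %max is taken:

* drop everything in the first ``post_hsct_exclusion_days`` (default
  30) after HSCT -- mixed chimerism there reflects engraftment;
* for relapsed transplants, drop everything later than
  ``pre_relapse_exclusion_days`` (default 30) before the relapse;
* for non-relapsed transplants, truncate at the same distance before
  the *average* relapse day of the relapsed group, so observation time
  is comparable between groups.

Both window boundaries are closed (a sample exactly at day 30 or
exactly at relapse - 30 is retained).  %max is the highest retained
percent-recipient value per transplant; transplants left with no
retained measurement are dropped from downstream denominators and
listed in a drop report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort


@dataclass
class FilterConfig:
    post_hsct_exclusion_days: int = 30
    pre_relapse_exclusion_days: int = 30
    average_kind: str = "mean"  # 'mean' or 'median'

    def __post_init__(self):
        if self.post_hsct_exclusion_days < 0 or \
                self.pre_relapse_exclusion_days < 0:
            raise ValueError("exclusion windows must be >= 0")
        if self.average_kind not in ("mean", "median"):
            raise ValueError("average_kind must be 'mean' or 'median'")


def average_time_to_relapse(cohort: Cohort, kind: str = "mean") -> float:
    """Average (mean or median) relapse day over relapsed transplants.

    Raises ``ValueError`` when the cohort has no relapses: the
    truncation day for non-relapsed transplants is then undefined.
    """
    days = cohort.transplants["relapse_day"].dropna().astype(float)
    if days.empty:
        raise ValueError("no relapsed transplants: the non-relapse "
                         "truncation day is undefined")
    if kind == "mean":
        return float(days.mean())
    if kind == "median":
        return float(days.median())
    raise ValueError("kind must be 'mean' or 'median'")


def apply_landmark_filter(cohort: Cohort, compartment: str, lineage: str,
                          config: FilterConfig | None = None) -> pd.DataFrame:
    """Measurements of one (compartment, lineage) stratum that survive
    the landmark filtration (closed boundaries).

    The non-relapse truncation day is recomputed from the cohort
    passed in, so running the analysis on an age subgroup uses that
    subgroup's own average relapse day.
    """
    if config is None:
        config = FilterConfig()
    m = cohort.measurements
    sub = m[(m["compartment"] == compartment) & (m["lineage"] == lineage)]
    if sub.empty:
        return sub.copy()

    avg_relapse = average_time_to_relapse(cohort, config.average_kind)
    relapse_map = cohort.transplants.set_index("transplant_id")["relapse_day"]
    rel_day = sub["transplant_id"].map(relapse_map).astype(float)  # NaN = none
    upper = np.where(np.isnan(rel_day),
                     avg_relapse - config.pre_relapse_exclusion_days,
                     rel_day - config.pre_relapse_exclusion_days)
    keep = (sub["day"] >= config.post_hsct_exclusion_days) & \
           (sub["day"].to_numpy() <= upper)
    return sub[keep].copy()


def compute_pct_max(retained: pd.DataFrame,
                    transplant_ids=None) -> tuple[pd.DataFrame, list[str]]:
    """Per-transplant %max over the retained measurements.

    Returns ``(summaries, dropped)`` where summaries has columns
    transplant_id, pct_max, day_of_pct_max (earliest day on ties) and
    n_samples_used, and ``dropped`` lists the ids from
    ``transplant_ids`` with zero retained measurements.
    """
    if retained.empty:
        summaries = pd.DataFrame(columns=["transplant_id", "pct_max",
                                          "day_of_pct_max", "n_samples_used"])
    else:
        ordered = retained.sort_values(
            ["transplant_id", "percent_recipient", "day"],
            ascending=[True, False, True])
        first = ordered.groupby("transplant_id", sort=True).first()
        counts = retained.groupby("transplant_id", sort=True).size()
        summaries = pd.DataFrame({
            "transplant_id": first.index,
            "pct_max": first["percent_recipient"].to_numpy(dtype=float),
            "day_of_pct_max": first["day"].to_numpy(dtype=np.int64),
            "n_samples_used": counts.to_numpy(dtype=np.int64),
        }).reset_index(drop=True)
    if transplant_ids is None:
        dropped: list[str] = []
    else:
        have = set(summaries["transplant_id"])
        dropped = [tid for tid in transplant_ids if tid not in have]
    return summaries, dropped


def relapse_day_snapshot(cohort: Cohort,
                         window_days: int = 3) -> pd.DataFrame:
    """Marrow measurements within +/- window_days of the relapse day of
    relapsed transplants (the values seen *at* relapse), with a
    ``lineage`` column for grouping."""
    if window_days < 0:
        raise ValueError("window_days must be >= 0")
    relapsed = cohort.transplants[cohort.relapsed_mask()]
    relapse_map = relapsed.set_index("transplant_id")["relapse_day"]
    m = cohort.measurements
    sub = m[(m["compartment"] == "marrow")
            & m["transplant_id"].isin(relapse_map.index)].copy()
    if sub.empty:
        return sub
    rel = sub["transplant_id"].map(relapse_map).astype(float)
    keep = (sub["day"] - rel).abs() <= window_days
    return sub[keep].reset_index(drop=True)
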