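"""Early complete donor chimerism (%min) and CC/MC risk stratification.

%min is the lowest recipient-chimerism value obtained during the first
``window_days`` (default 60, inclusive) after HSCT in the configured
compartment (default blood).  A transplant achieves early complete
chimerism (CC) when %min falls *strictly below* the cutoff; otherwise
it is mixed chimerism (MC).  Transplants that relapse within the early
window are removed before the analysis (their outcome precedes the
landmark).

Published CD3/CD19/CD33 cutoffs for the all/pediatric/adult subsets
ship as named presets; a cutoff can also be re-derived from data via
the ROC/Youden machinery.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cohort import Cohort

# cutoff presets (percent recipient) by (lineage, age group):
# blood %min thresholds below which early complete chimerism is called
CUTOFF_PRESETS: dict[tuple[str, str], float] = {
    ("CD19", "all"): 0.01,
    ("CD3", "all"): 0.3,
    ("CD33", "all"): 0.06,
    ("CD19", "pediatric"): 0.2,
    ("CD3", "pediatric"): 0.9,
    ("CD33", "pediatric"): 0.06,
    ("CD19", "adult"): 0.01,
    ("CD3", "adult"): 0.12,
    ("CD33", "adult"): 0.1,
}


@dataclass
class EarlyWindowConfig:
    window_days: int = 60
    compartment: str = "blood"

    def __post_init__(self):
        if self.window_days <= 0:
            raise ValueError("window_days must be > 0")
        if self.compartment not in ("blood", "marrow"):
            raise ValueError("compartment must be 'blood' or 'marrow'")


def exclude_early_relapses(cohort: Cohort,
                           config: EarlyWindowConfig | None = None) -> Cohort:
    """Remove transplants whose relapse falls inside the early window
    (relapse_day <= window_days); everything else is retained."""
    if config is None:
        config = EarlyWindowConfig()
    t = cohort.transplants
    early = t["relapse_day"].notna() & (t["relapse_day"] <= config.window_days)
    keep = t[~early].reset_index(drop=True)
    ids = set(keep["transplant_id"])
    meas = cohort.measurements[
        cohort.measurements["transplant_id"].isin(ids)].reset_index(drop=True)
    return Cohort(keep, meas)


def compute_pct_min(cohort: Cohort, lineage: str,
                    config: EarlyWindowConfig | None = None,
                    ) -> tuple[pd.DataFrame, list[str]]:
    """Per-transplant %min over the early window.

    Returns ``(pct_min_frame, omitted)``: the frame has columns
    transplant_id, pct_min and n_samples_used; ``omitted`` lists
    transplants with no qualifying measurement (wrong compartment or
    no sample in the window), which the analysis must skip.
    """
    if config is None:
        config = EarlyWindowConfig()
    m = cohort.measurements
    sub = m[(m["compartment"] == config.compartment)
            & (m["lineage"] == lineage)
            & (m["day"] >= 0) & (m["day"] <= config.window_days)]
    if sub.empty:
        frame = pd.DataFrame(columns=["transplant_id", "pct_min",
                                      "n_samples_used"])
    else:
        grp = sub.groupby("transplant_id", sort=True)["percent_recipient"]
        frame = pd.DataFrame({
            "transplant_id": grp.min().index,
            "pct_min": grp.min().to_numpy(dtype=float),
            "n_samples_used": grp.size().to_numpy(),
        }).reset_index(drop=True)
    have = set(frame["transplant_id"])
    omitted = [tid for tid in cohort.transplants["transplant_id"]
               if tid not in have]
    return frame, omitted


def dichotomize_cc(pct_min_frame: pd.DataFrame,
                   cutoff: float) -> pd.DataFrame:
    """Label each transplant CC iff pct_min < cutoff (strict), else MC.

    Returns a copy of the input with ``label`` and ``cutoff_used``
    columns added.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    out = pct_min_frame.copy()
    out["label"] = pd.Series(
        ["CC" if v < cutoff else "MC" for v in out["pct_min"]],
        index=out.index, dtype=object)
    out["cutoff_used"] = float(cutoff)
    return out


def preset_cutoff(lineage: str, age_group: str) -> float:
    """Published blood %min cutoff for a (lineage, age group) pair."""
    try:
        return CUTOFF_PRESETS[(lineage, age_group)]
    except KeyError:
        raise KeyError(f"no cutoff preset for lineage={lineage!r}, "
                       f"age_group={age_group!r}") from None
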