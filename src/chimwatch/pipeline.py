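"""End-to-end analyses and machine-readable reports.

Three headline analyses, each returning a plain-dict report section so
that every number is JSON-serializable and traceable to a single
stat-engine call:

* ``run_maxchim_analysis`` -- landmark filtration, %max per
  transplant, per-lineage univariable logistic fits, a multivariable
  fit for the configured lineage plus covariates, and the ROC/Youden
  cutoff with sensitivity/specificity.
* ``run_early_cc_analysis`` -- early-window %min, CC/MC
  dichotomization (derived or fixed cutoff), association tests, and
  Kaplan-Meier relapse-free curves per group with the log-rank test
  and 2-year estimates.
* ``run_kinetics`` -- LOESS chimerism kinetics of relapsed
  transplants with time re-indexed so relapse is at day 0 (T cell
  lineage vs the leukemia lineage, per compartment).

p-values throughout are reported without multiple-testing adjustment.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import stats as st
from .cohort import (BLOOD_LINEAGES, MARROW_LINEAGES, Cohort,
                     paired_correlation, paired_samples)
from .earlycc import (EarlyWindowConfig, compute_pct_min, dichotomize_cc,
                      exclude_early_relapses)
from .landmark import (FilterConfig, apply_landmark_filter,
                       average_time_to_relapse, compute_pct_max)

TWO_YEARS_DAYS = 730

_COVARIATE_BUILDERS = {
    "age_years": ("age_years", lambda t: t["age_years"].to_numpy(float)),
    "conditioning": ("mac_vs_ric",
                     lambda t: (t["conditioning"] == "MAC").to_numpy(float)),
    "source": ("bm_vs_pb", lambda t: (t["source"] == "BM").to_numpy(float)),
    "atg": ("atg", lambda t: t["atg"].to_numpy(float)),
}


@dataclass
class AnalysisConfig:
    age_group: str = "all"               # all | pediatric | adult
    compartment: str = "marrow"
    lineage: str = "CD3"
    filter: FilterConfig = field(default_factory=FilterConfig)
    early: EarlyWindowConfig = field(default_factory=EarlyWindowConfig)
    cutoff_mode: str = "youden"          # 'youden' or 'fixed'
    fixed_cutoff: float | None = None
    covariates: tuple[str, ...] = ("age_years", "conditioning", "source",
                                   "atg")
    horizon_days: int = TWO_YEARS_DAYS

    def __post_init__(self):
        if self.age_group not in ("all", "pediatric", "adult"):
            raise ValueError("age_group must be all|pediatric|adult")
        if self.cutoff_mode not in ("youden", "fixed"):
            raise ValueError("cutoff_mode must be 'youden' or 'fixed'")
        if self.cutoff_mode == "fixed":
            if self.fixed_cutoff is None or self.fixed_cutoff <= 0:
                raise ValueError("fixed cutoff must be a positive percent")
        unknown = set(self.covariates) - set(_COVARIATE_BUILDERS)
        if unknown:
            raise ValueError(f"unknown covariates: {sorted(unknown)}")


def _logistic_block(fit: st.LogisticFit) -> dict:
    return {
        "names": list(fit.names),
        "coef": [float(v) for v in fit.coef],
        "se": [float(v) for v in fit.se],
        "odds_ratios": [float(v) for v in fit.odds_ratios],
        "ci_lower": [float(v) for v in fit.ci_lower],
        "ci_upper": [float(v) for v in fit.ci_upper],
        "p_values": [float(v) for v in fit.p_values],
        "n_obs": fit.n_obs,
        "converged": fit.converged,
        "separation": fit.separation,
    }


def _km_block(curve: st.SurvivalCurve, horizon_days: int) -> dict:
    at_h = st.survival_at(curve, horizon_days)
    return {
        "times": [float(v) for v in curve.times],
        "survival": [float(v) for v in curve.survival],
        "ci_lower": [float(v) for v in curve.ci_lower],
        "ci_upper": [float(v) for v in curve.ci_upper],
        "n_at_risk": [int(v) for v in curve.n_at_risk],
        "n_events": [int(v) for v in curve.n_events],
        "n_units": curve.n_units,
        "horizon_days": horizon_days,
        "survival_at_horizon": at_h.estimate,
        "ci_at_horizon": [at_h.ci_lower, at_h.ci_upper],
        "extrapolated_at_horizon": at_h.extrapolated,
    }


def _relapse_outcomes(cohort: Cohort) -> pd.DataFrame:
    t = cohort.transplants
    relapsed = t["relapse_day"].notna()
    return pd.DataFrame({
        "transplant_id": t["transplant_id"],
        "relapse": relapsed.astype(int),
        "time": np.where(relapsed, t["relapse_day"].astype(float),
                         t["censor_day"].astype(float)),
    })


def _covariate_frame(transplants: pd.DataFrame,
                     covariates) -> tuple[pd.DataFrame, list[str]]:
    """Coded covariate columns; constant columns are dropped (too few
    occurrences to estimate) and reported."""
    cols = {}
    dropped = []
    for cov in covariates:
        name, build = _COVARIATE_BUILDERS[cov]
        vals = build(transplants)
        if np.ptp(vals) == 0.0:
            dropped.append(name)
        else:
            cols[name] = vals
    frame = pd.DataFrame(cols, index=transplants.index)
    return frame, dropped


def run_maxchim_analysis(cohort: Cohort, config: AnalysisConfig) -> dict:
    """Landmark %max relapse-prediction analysis for one age group."""
    sub = cohort.subset_age(config.age_group)
    section: dict = {
        "analysis": "maxchim",
        "age_group": config.age_group,
        "compartment": config.compartment,
        "lineage": config.lineage,
        "n_transplants": sub.n_transplants,
    }
    n_relapse = int(sub.relapsed_mask().sum())
    if n_relapse < 2:
        section["skipped"] = (f"insufficient relapses in subset "
                              f"(n={n_relapse} < 2)")
        return section
    section["avg_relapse_day"] = average_time_to_relapse(
        sub, config.filter.average_kind)

    lineages = (MARROW_LINEAGES if config.compartment == "marrow"
                else BLOOD_LINEAGES)
    relapse_map = sub.transplants.set_index("transplant_id")["relapse_day"]
    univariable = {}
    drop_reports = {}
    selected = None
    for lineage in lineages:
        retained = apply_landmark_filter(sub, config.compartment, lineage,
                                         config.filter)
        summaries, dropped = compute_pct_max(
            retained, list(sub.transplants["transplant_id"]))
        drop_reports[lineage] = {"n_analyzed": len(summaries),
                                 "n_dropped": len(dropped),
                                 "dropped": dropped}
        if summaries.empty:
            univariable[lineage] = {"skipped": "no retained measurements"}
            continue
        y = summaries["transplant_id"].map(relapse_map).notna().astype(int)
        if y.sum() < 2 or (1 - y).sum() < 1:
            univariable[lineage] = {
                "skipped": f"insufficient class balance (relapses={int(y.sum())})"}
            continue
        fit = st.logistic_fit(summaries[["pct_max"]].to_numpy(), y.to_numpy(),
                              names=["pct_max"])
        univariable[lineage] = _logistic_block(fit)
        if lineage == config.lineage:
            selected = (summaries, y)
    section["univariable"] = univariable
    section["drop_reports"] = drop_reports

    if selected is None:
        section["skipped"] = (f"no analyzable data for selected lineage "
                              f"{config.lineage}")
        return section
    summaries, y = selected

    # multivariable: selected lineage %max plus configured covariates
    merged = summaries.merge(sub.transplants, on="transplant_id", how="left")
    cov_frame, dropped_cov = _covariate_frame(merged, config.covariates)
    design = pd.concat(
        [summaries[["pct_max"]].reset_index(drop=True),
         cov_frame.reset_index(drop=True)], axis=1)
    try:
        multi = st.logistic_fit(design.to_numpy(), y.to_numpy(),
                                names=list(design.columns))
        section["multivariable"] = _logistic_block(multi)
    except (ValueError, RuntimeError) as exc:
        section["multivariable"] = {"skipped": str(exc)}
    section["covariates_dropped"] = dropped_cov

    roc_res = st.roc(summaries["pct_max"].to_numpy(), y.to_numpy())
    section["roc"] = {
        "auc": roc_res.auc,
        "youden_cutoff": roc_res.youden_cutoff,
        "j_at_cutoff": roc_res.j_at_cutoff,
        "sensitivity": roc_res.sensitivity_at_cutoff,
        "specificity": roc_res.specificity_at_cutoff,
        "n_pos": roc_res.n_pos,
        "n_neg": roc_res.n_neg,
        "thresholds": [float(v) if np.isfinite(v) else None
                       for v in roc_res.thresholds],
        "tpr": [float(v) for v in roc_res.tpr],
        "fpr": [float(v) for v in roc_res.fpr],
    }
    return section


def run_early_cc_analysis(cohort: Cohort, config: AnalysisConfig) -> dict:
    """Early complete-chimerism risk stratification for one age group."""
    sub = cohort.subset_age(config.age_group)
    eligible = exclude_early_relapses(sub, config.early)
    section: dict = {
        "analysis": "early_cc",
        "age_group": config.age_group,
        "compartment": config.early.compartment,
        "lineage": config.lineage,
        "window_days": config.early.window_days,
        "n_transplants": sub.n_transplants,
        "n_excluded_early_relapse": sub.n_transplants - eligible.n_transplants,
    }
    pct_min, omitted = compute_pct_min(eligible, config.lineage, config.early)
    section["n_without_window_data"] = len(omitted)
    if pct_min.empty:
        section["skipped"] = "no transplants with early-window measurements"
        return section

    outcomes = _relapse_outcomes(eligible).set_index("transplant_id")
    merged = pct_min.merge(outcomes, left_on="transplant_id",
                           right_index=True, how="left")
    y = merged["relapse"].to_numpy(int)
    if y.sum() < 2 or (1 - y).sum() < 1:
        section["skipped"] = (f"insufficient relapses among analyzable "
                              f"transplants (n={int(y.sum())})")
        return section

    scores = merged["pct_min"].to_numpy(float)
    roc_res = st.roc(scores, y)
    section["pct_min_roc"] = {"auc": roc_res.auc,
                              "youden_cutoff": roc_res.youden_cutoff,
                              "sensitivity": roc_res.sensitivity_at_cutoff,
                              "specificity": roc_res.specificity_at_cutoff}
    if config.cutoff_mode == "fixed":
        cutoff = float(config.fixed_cutoff)
    else:
        cutoff = roc_res.youden_cutoff
    section["cutoff_mode"] = config.cutoff_mode
    section["cutoff_used"] = cutoff

    labelled = dichotomize_cc(merged, cutoff)
    is_cc = (labelled["label"] == "CC").to_numpy()
    section["n_cc"] = int(is_cc.sum())
    section["n_mc"] = int((~is_cc).sum())

    # association between early CC and relapse
    table = np.array([
        [int((is_cc & (y == 1)).sum()), int((is_cc & (y == 0)).sum())],
        [int((~is_cc & (y == 1)).sum()), int((~is_cc & (y == 0)).sum())],
    ])
    section["cc_by_relapse_table"] = table.tolist()
    fisher = st.fisher_exact(table)
    section["fisher_p"] = fisher.p_value
    try:
        chi2 = st.chi2_test(table)
        section["chi2_p"] = chi2.p_value
    except ValueError as exc:
        section["chi2_p"] = None
        section["chi2_note"] = str(exc)
    if 0 < is_cc.sum() < is_cc.size:
        fit = st.logistic_fit(is_cc.astype(float)[:, None], y,
                              names=["early_cc"])
        section["logistic"] = _logistic_block(fit)
    else:
        section["logistic"] = {"skipped": "all transplants in one CC class"}

    if is_cc.all() or (~is_cc).all():
        section["km"] = {"skipped": "all transplants in one CC class"}
        return section
    times = labelled["time"].to_numpy(float)
    events = y.astype(bool)
    curve_cc = st.km(times[is_cc], events[is_cc])
    curve_mc = st.km(times[~is_cc], events[~is_cc])
    lr = st.logrank(times[is_cc], events[is_cc], times[~is_cc], events[~is_cc])
    section["km"] = {
        "CC": _km_block(curve_cc, config.horizon_days),
        "MC": _km_block(curve_mc, config.horizon_days),
        "logrank_statistic": lr.statistic,
        "logrank_p": lr.p_value,
    }
    return section


def run_kinetics(cohort: Cohort, disease_lineage: str = "CD19",
                 span: float = 0.75, window_days: int = 730,
                 grid_step: int = 7) -> dict:
    """LOESS chimerism kinetics aligned at relapse (day 0).

    Pools all measurements of relapsed transplants from ``window_days``
    before relapse, separately per compartment for CD3 and the disease
    lineage, and fits a LOESS curve to each pool.
    """
    relapsed = cohort.transplants[cohort.relapsed_mask()]
    section: dict = {"analysis": "kinetics",
                     "disease_lineage": disease_lineage,
                     "n_relapsed": len(relapsed)}
    if relapsed.empty:
        section["skipped"] = "no relapsed transplants"
        return section
    relapse_map = relapsed.set_index("transplant_id")["relapse_day"]
    m = cohort.measurements
    m = m[m["transplant_id"].isin(relapse_map.index)].copy()
    m["days_to_relapse"] = (
        m["day"] - m["transplant_id"].map(relapse_map).astype(float))
    m = m[(m["days_to_relapse"] >= -window_days)
          & (m["days_to_relapse"] <= 0)]

    curves = {}
    for compartment in ("blood", "marrow"):
        for lineage in ("CD3", disease_lineage):
            sel = m[(m["compartment"] == compartment)
                    & (m["lineage"] == lineage)]
            key = f"{compartment}_{lineage}"
            if len(sel) < 4 or sel["days_to_relapse"].nunique() < 3:
                curves[key] = {"skipped":
                               f"too few points (n={len(sel)})"}
                continue
            x = sel["days_to_relapse"].to_numpy(float)
            yv = sel["percent_recipient"].to_numpy(float)
            grid = np.arange(int(np.floor(x.min())), 0 + 1, grid_step,
                             dtype=float)
            fitted = st.loess_fit(x, yv, grid, span=span, degree=1)
            curves[key] = {
                "grid": [float(v) for v in grid],
                "fitted": [float(v) for v in fitted],
                "n_points": int(len(sel)),
            }
    section["curves"] = curves
    return section


def run_full(cohort: Cohort, config: AnalysisConfig,
             disease_lineage: str = "CD19") -> dict:
    """All report sections on one cohort/config; deterministic."""
    report: dict = {
        "metadata": {
            "n_transplants": cohort.n_transplants,
            "n_measurements": int(len(cohort.measurements)),
            "n_relapsed": int(cohort.relapsed_mask().sum()),
            "age_group": config.age_group,
            "note": ("p-values are presented without correction for "
                     "multiple testing"),
        },
    }
    pairs = paired_samples(cohort, "CD3")
    try:
        corr = paired_correlation(pairs)
        report["paired_correlation"] = {"lineage": "CD3", "r": corr.r,
                                        "n": corr.n}
    except ValueError as exc:
        report["paired_correlation"] = {"lineage": "CD3",
                                        "skipped": str(exc)}
    report["maxchim"] = run_maxchim_analysis(cohort, config)
    report["early_cc"] = run_early_cc_analysis(cohort, config)
    report["kinetics"] = run_kinetics(cohort, disease_lineage)
    return report


# ---------------------------------------------------------------------------
# report serialization
# ---------------------------------------------------------------------------


def report_json(report: dict) -> str:
    return json.dumps(report, indent=2, sort_keys=True, allow_nan=False)


def write_report(report: dict, out_dir) -> None:
    """Write report.json plus flat TSV extracts (roc_points.tsv,
    km_curves.tsv, logistic_fits.tsv)."""
    os.makedirs(out_dir, exist_ok=True)
    with open(os.path.join(out_dir, "report.json"), "w") as fh:
        fh.write(report_json(report))
        fh.write("\n")

    roc_block = report.get("maxchim", {}).get("roc")
    if roc_block:
        pd.DataFrame({
            "threshold": roc_block["thresholds"],
            "tpr": roc_block["tpr"],
            "fpr": roc_block["fpr"],
        }).to_csv(os.path.join(out_dir, "roc_points.tsv"), sep="\t",
                  index=False)

    km_rows = []
    km_block = report.get("early_cc", {}).get("km")
    if km_block and "skipped" not in km_block:
        for group in ("CC", "MC"):
            blk = km_block[group]
            for i, t in enumerate(blk["times"]):
                km_rows.append({
                    "group": group, "time": t,
                    "survival": blk["survival"][i],
                    "ci_lower": blk["ci_lower"][i],
                    "ci_upper": blk["ci_upper"][i],
                    "n_at_risk": blk["n_at_risk"][i],
                })
    if km_rows:
        pd.DataFrame(km_rows).to_csv(
            os.path.join(out_dir, "km_curves.tsv"), sep="\t", index=False)

    fit_rows = []

    def _collect(block, analysis, model):
        if not block or "skipped" in block:
            return
        for i, name in enumerate(block["names"]):
            fit_rows.append({
                "analysis": analysis, "model": model, "term": name,
                "odds_ratio": block["odds_ratios"][i],
                "ci_lower": block["ci_lower"][i],
                "ci_upper": block["ci_upper"][i],
                "p_value": block["p_values"][i],
                "n_obs": block["n_obs"],
            })

    maxchim = report.get("maxchim", {})
    for lineage, blk in maxchim.get("univariable", {}).items():
        _collect(blk, "maxchim", f"univariable_{lineage}")
    _collect(maxchim.get("multivariable"), "maxchim", "multivariable")
    _collect(report.get("early_cc", {}).get("logistic"), "early_cc",
             "univariable")
    if fit_rows:
        pd.DataFrame(fit_rows).to_csv(
            os.path.join(out_dir, "logistic_fits.tsv"), sep="\t", index=False)
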