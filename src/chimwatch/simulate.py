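"""Synthetic post-HSCT chimerism cohort generator.

Emulates the longitudinal structure of lineage-specific chimerism
monitoring after allogeneic HSCT for B-ALL so that every downstream
analysis stage can be exercised without clinical data:

* ~20% of transplants relapse, at a log-normal time with median 264
  days; follow-up 1-16.8 years.
* clinician-driven irregular sampling: per-compartment renewal
  processes, denser during the engraftment phase, with long-run median
  inter-sample intervals of ~39 days (blood) and ~80 days (marrow);
  first sample around engraftment (day 17-21); sampling stops at
  relapse, with an optional diagnostic work-up sample at relapse.
* kinetics: engraftment-phase mixed chimerism decaying exponentially
  toward complete donor chimerism; a transient pre-relapse bump in
  CD3+ (T cell) recipient chimerism (raised-cosine pulse peaking
  halfway through the pre-relapse window); a terminal surge in the
  leukemia lineage (CD19+ for B-ALL) peaking at relapse; an additive
  recipient-percent offset in marrow relative to blood (compartment
  discordance); multiplicative log-normal measurement noise; values
  below the limit of detection reported as 0.

An optional ``cc_failure_link`` ties failure to achieve early complete
donor chimerism to a higher relapse probability: a latent fraction of
transplants retains a persistent recipient-chimerism plateau, and the
two latent groups receive relapse probabilities inverted from target
2-year relapse-free survival values.  It is off by default; with it
off, early chimerism and relapse are independent by construction
(null calibration).

Determinism: one root seed; per-transplant substreams are spawned as
``SeedSequence(seed, spawn_key=(index,))`` so cohorts are reproducible
and insensitive to transplant reordering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import BLOOD_LINEAGES, MARROW_LINEAGES, Cohort, cohort_from_frames

__all__ = [
    "SamplingParams",
    "KineticsParams",
    "CcFailureLink",
    "SimulationParams",
    "TrajectoryState",
    "default_params",
    "draw_trajectory",
    "chimerism_value",
    "noise_free_value",
    "generate_cohort",
]

_LN2 = math.log(2.0)
TWO_YEARS_DAYS = 730.0


@dataclass
class SamplingParams:
    """Clinician-driven sampling schedule (renewal process per
    compartment, denser during the engraftment phase)."""

    blood_interval_days: float = 39.0       # long-run median (blood)
    marrow_interval_days: float = 80.0      # long-run median (marrow)
    blood_early_interval_days: float = 12.0
    marrow_early_interval_days: float = 28.0
    early_phase_end_day: float = 100.0
    first_sample_day_range: tuple[int, int] = (17, 21)
    monitoring_days: float = 540.0          # routine monitoring horizon
    relapse_workup_prob: float = 0.8        # extra sample at relapse day


@dataclass
class KineticsParams:
    """Latent trajectory shape and measurement-noise parameters.

    All values are on the percent-recipient scale (0-100).
    """

    engraftment_start_percent: float = 40.0   # recipient % at day 0
    start_sigma_log: float = 0.25             # per-transplant variation
    engraftment_decay_halflife: float = 5.5   # days
    halflife_sigma_log: float = 0.10
    noise_sd_log: float = 0.35                # multiplicative log-normal
    noise_floor_offset: float = 0.02          # percent added before noise
    lod_percent: float = 0.01                 # below this -> reported 0
    marrow_blood_offset: float = 0.5          # additive percent in marrow
    cd3_bump_amplitude: float = 2.0           # transient pre-relapse T cell rise
    cd3_bump_onset_before_relapse: float = 180.0
    leukemia_surge_amplitude: float = 40.0    # terminal disease-lineage surge
    surge_onset_before_relapse: float = 30.0
    mc_plateau_percent: float = 1.5           # persistent mixed chimerism


@dataclass
class CcFailureLink:
    """Optional link between failed early donor-chimerism clearance and
    relapse risk (latent two-group mixture)."""

    enabled: bool = False
    mc_fraction: float = 0.30
    relapse_prob_cc: float = 0.121   # from_rfs_targets(0.90, 0.65) values
    relapse_prob_mc: float = 0.417

    @classmethod
    def from_rfs_targets(cls, rfs2_cc: float, rfs2_mc: float,
                         relapse_day_median: float = 264.0,
                         relapse_day_sigma_log: float = 0.9,
                         mc_fraction: float = 0.30,
                         exclusion_window_days: float = 60.0,
                         ) -> "CcFailureLink":
        """Invert target 2-year relapse-free survival per latent group.

        With relapse times log-normal (median m, log-sd s), a group
        relapse probability p, and the early-CC convention of removing
        transplants that relapse within the first
        ``exclusion_window_days``, relapse-free survival among the
        eligible transplants is

            S(730) = (1 - p F(730)) / (1 - p F(w)),

        so the probability hitting a target S is
        p = (1 - S) / (F(730) - S F(w)).
        """
        def lognorm_cdf(t: float) -> float:
            z = math.log(t / relapse_day_median) / relapse_day_sigma_log
            return 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))

        f730 = lognorm_cdf(TWO_YEARS_DAYS)
        fw = lognorm_cdf(exclusion_window_days)
        return cls(
            enabled=True,
            mc_fraction=mc_fraction,
            relapse_prob_cc=(1.0 - rfs2_cc) / (f730 - rfs2_cc * fw),
            relapse_prob_mc=(1.0 - rfs2_mc) / (f730 - rfs2_mc * fw),
        )


@dataclass
class SimulationParams:
    """Study-level simulation conditions.

    Defaults encode the cohort structure the analysis assumes: 138
    transplants, 51/138 pediatric, 20% relapse probability, relapse
    days log-normal with median 264, follow-up uniform on 1-16.8
    years.
    """

    n_transplants: int = 138
    pediatric_fraction: float = 51.0 / 138.0
    relapse_prob: float = 0.20
    relapse_day_median_days: float = 264.0
    relapse_day_sigma_log: float = 0.9
    followup_years: tuple[float, float] = (1.0, 16.8)
    disease_lineage: str = "CD19"             # B-ALL
    sampling: SamplingParams = field(default_factory=SamplingParams)
    kinetics: KineticsParams = field(default_factory=KineticsParams)
    cc_link: CcFailureLink = field(default_factory=CcFailureLink)
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.pediatric_fraction <= 1.0:
            raise ValueError("pediatric_fraction must be in [0, 1]")
        if not 0.0 <= self.relapse_prob <= 1.0:
            raise ValueError("relapse_prob must be in [0, 1]")
        k = self.kinetics
        for name in ("cd3_bump_amplitude", "leukemia_surge_amplitude",
                     "mc_plateau_percent", "noise_sd_log"):
            if getattr(k, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("engraftment_decay_halflife",
                     "cd3_bump_onset_before_relapse",
                     "surge_onset_before_relapse"):
            if getattr(k, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        s = self.sampling
        for name in ("blood_interval_days", "marrow_interval_days",
                     "blood_early_interval_days",
                     "marrow_early_interval_days", "monitoring_days"):
            if getattr(s, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def default_params(seed: int = 0) -> SimulationParams:
    """Default study conditions (see class docstring)."""
    return SimulationParams(seed=seed)


@dataclass
class TrajectoryState:
    """Per-transplant latent state; deterministic given (params, seed,
    transplant index)."""

    index: int
    pediatric: bool
    age_years: float
    followup_day: int
    latent_relapse: bool
    relapse_day: int | None        # latent relapse time (may exceed follow-up)
    observed_relapse: bool         # relapse_day <= followup_day
    is_mc: bool                    # latent persistent-mixed-chimerism group
    plateau_percent: float
    start_percent: float
    halflife_days: float
    conditioning: str = "MAC"
    atg: int = 0
    source: str = "PB"
    donor: str = "MUD"

    def no_relapse_clone(self) -> "TrajectoryState":
        """Same kinetics, relapse removed (for counterfactual checks)."""
        return replace(self, latent_relapse=False, relapse_day=None,
                       observed_relapse=False)


def _transplant_rng(params: SimulationParams, index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(params.seed, spawn_key=(index,)))


# covariate frequencies by age group, approximating a mixed
# pediatric/adult allo-HSCT case mix
_COVARIATE_FREQS = {
    "pediatric": {"mac": 0.94, "atg": 0.57, "pb": 0.18,
                  "donor_p": (0.29, 0.10, 0.61)},
    "adult": {"mac": 0.63, "atg": 0.66, "pb": 0.91,
              "donor_p": (0.30, 0.05, 0.65)},
}


def draw_trajectory(params: SimulationParams, index: int,
                    rng: np.random.Generator | None = None) -> TrajectoryState:
    """Draw the latent per-transplant state from its own substream."""
    if rng is None:
        rng = _transplant_rng(params, index)
    k = params.kinetics

    pediatric = rng.random() < params.pediatric_fraction
    if pediatric:
        age = float(rng.integers(2, 18))
    else:
        age = float(rng.integers(18, 70))
    freqs = _COVARIATE_FREQS["pediatric" if pediatric else "adult"]
    conditioning = "MAC" if rng.random() < freqs["mac"] else "RIC"
    atg = int(rng.random() < freqs["atg"])
    source = "PB" if rng.random() < freqs["pb"] else "BM"
    donor = ["SIB", "HAPLO", "MUD"][int(rng.choice(3, p=freqs["donor_p"]))]

    lo_y, hi_y = params.followup_years
    followup_day = int(round(rng.uniform(lo_y, hi_y) * 365.25))

    if params.cc_link.enabled:
        is_mc = rng.random() < params.cc_link.mc_fraction
        p_rel = (params.cc_link.relapse_prob_mc if is_mc
                 else params.cc_link.relapse_prob_cc)
    else:
        is_mc = False
        p_rel = params.relapse_prob
        rng.random()  # keep stream alignment with the linked case
    plateau = k.mc_plateau_percent if is_mc else 0.0

    latent_relapse = rng.random() < p_rel
    relapse_day: int | None = None
    if latent_relapse:
        relapse_day = max(1, int(round(
            params.relapse_day_median_days
            * math.exp(params.relapse_day_sigma_log * rng.standard_normal()))))

    start = k.engraftment_start_percent * math.exp(
        k.start_sigma_log * rng.standard_normal())
    halflife = k.engraftment_decay_halflife * math.exp(
        k.halflife_sigma_log * rng.standard_normal())

    return TrajectoryState(
        index=index,
        pediatric=pediatric,
        age_years=age,
        followup_day=followup_day,
        latent_relapse=latent_relapse,
        relapse_day=relapse_day,
        observed_relapse=bool(latent_relapse
                              and relapse_day <= followup_day),
        is_mc=is_mc,
        plateau_percent=plateau,
        start_percent=start,
        halflife_days=halflife,
        conditioning=conditioning,
        atg=atg,
        source=source,
        donor=donor,
    )


def noise_free_value(params: SimulationParams, state: TrajectoryState,
                     lineage: str, compartment: str, day: float) -> float:
    """Latent percent-recipient value before noise and detection floor."""
    if day < 0:
        raise ValueError("day must be >= 0")
    k = params.kinetics
    v = state.start_percent * 2.0 ** (-day / state.halflife_days)
    v += state.plateau_percent
    if state.latent_relapse and state.relapse_day is not None:
        r = state.relapse_day
        if lineage == "CD3" and k.cd3_bump_amplitude > 0:
            w = k.cd3_bump_onset_before_relapse
            if r - w <= day <= r:
                # raised-cosine pulse, zero at both window ends,
                # peak amplitude at the window midpoint
                v += k.cd3_bump_amplitude * 0.5 * (
                    1.0 - math.cos(2.0 * math.pi * (day - (r - w)) / w))
        if lineage == params.disease_lineage and k.leukemia_surge_amplitude > 0:
            w = k.surge_onset_before_relapse
            if r - w <= day <= r:
                # half-cosine ramp peaking at the relapse day
                v += k.leukemia_surge_amplitude * 0.5 * (
                    1.0 - math.cos(math.pi * (day - (r - w)) / w))
    if compartment == "marrow":
        v += k.marrow_blood_offset
    return float(min(max(v, 0.0), 100.0))


def chimerism_value(params: SimulationParams, state: TrajectoryState,
                    lineage: str, compartment: str, day: float,
                    rng: np.random.Generator | None = None,
                    ) -> tuple[float, bool]:
    """One measured value: latent value, multiplicative log-normal noise
    (applied to percent + a small floor offset), limit-of-detection
    floor (below it the lab reports 0), clamped to [0, 100].

    Returns ``(percent_recipient, below_detection)``.  With ``rng``
    None or ``noise_sd_log == 0`` the value is noise-free.
    """
    k = params.kinetics
    v = noise_free_value(params, state, lineage, compartment, day)
    if rng is not None and k.noise_sd_log > 0:
        c = k.noise_floor_offset
        v = max(0.0, (v + c) * math.exp(k.noise_sd_log * rng.standard_normal()) - c)
    below = v < k.lod_percent
    if below:
        v = 0.0
    return float(min(v, 100.0)), below


def _sampling_days(params: SimulationParams, rng: np.random.Generator,
                   compartment: str, end_day: float) -> list[int]:
    s = params.sampling
    if compartment == "blood":
        base, early = s.blood_interval_days, s.blood_early_interval_days
    else:
        base, early = s.marrow_interval_days, s.marrow_early_interval_days
    lo, hi = s.first_sample_day_range
    day = float(rng.integers(lo, hi + 1))
    days: list[int] = []
    # gamma(3) renewal gaps: irregular but without the extreme long
    # gaps of an exponential (clinical schedules are loosely regular);
    # scale chosen so the gap median matches the configured interval
    gamma_shape = 3.0
    gamma_median_factor = 2.674  # median of gamma(3, 1)
    while day <= end_day:
        days.append(int(round(day)))
        median = early if day < s.early_phase_end_day else base
        day += max(1.0, rng.gamma(gamma_shape, median / gamma_median_factor))
    return sorted(set(days))


def generate_cohort(params: SimulationParams) -> Cohort:
    """Generate a full synthetic cohort (deterministic given seed)."""
    params.validate()
    t_rows = []
    m_rows = []
    for i in range(params.n_transplants):
        rng = _transplant_rng(params, i)
        state = draw_trajectory(params, i, rng)

        relapse_day = state.relapse_day if state.observed_relapse else None
        end_day = min(params.sampling.monitoring_days, state.followup_day)
        if relapse_day is not None:
            end_day = min(end_day, relapse_day)

        tid = f"T{i + 1:04d}"
        t_rows.append({
            "transplant_id": tid,
            "patient_id": f"P{i + 1:04d}",
            "age_years": state.age_years,
            "relapse_day": relapse_day,
            "censor_day": state.followup_day,
            "conditioning": state.conditioning,
            "atg": state.atg,
            "source": state.source,
            "donor": state.donor,
        })

        for compartment, lineages in (("blood", BLOOD_LINEAGES),
                                      ("marrow", MARROW_LINEAGES)):
            days = _sampling_days(params, rng, compartment, end_day)
            if (relapse_day is not None
                    and rng.random() < params.sampling.relapse_workup_prob
                    and relapse_day not in days):
                days = sorted(days + [relapse_day])
            for day in days:
                for lineage in lineages:
                    value, below = chimerism_value(
                        params, state, lineage, compartment, day, rng)
                    m_rows.append({
                        "transplant_id": tid,
                        "day": day,
                        "compartment": compartment,
                        "lineage": lineage,
                        "percent_recipient": value,
                        "below_detection": int(below),
                    })

    transplants = pd.DataFrame(
        t_rows, columns=["transplant_id", "patient_id", "age_years",
                         "relapse_day", "censor_day", "conditioning", "atg",
                         "source", "donor"])
    measurements = pd.DataFrame(
        m_rows, columns=["transplant_id", "day", "compartment", "lineage",
                         "percent_recipient", "below_detection"])
    return cohort_from_frames(transplants, measurements, validate=False)
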