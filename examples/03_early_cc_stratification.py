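"""Early complete-chimerism risk stratification.

Simulates a cohort in which failure to clear recipient hematopoiesis
early (a persistent mixed-chimerism plateau) carries a higher relapse
probability, designed so the latent groups have 2-year relapse-free
survival of 0.90 vs 0.65.  The analysis then recovers that contrast
from the measurements alone: %min over the first 60 days of blood
CD3+ chimerism, a Youden-derived CC cutoff, and Kaplan-Meier curves
per group compared by the log-rank test.
"""

import chimwatch as cw

params = cw.default_params(seed=11)
params.n_transplants = 500
params.kinetics.cd3_bump_amplitude = 0.0  # isolate the early-CC effect
params.cc_link = cw.CcFailureLink.from_rfs_targets(0.90, 0.65,
                                                   mc_fraction=0.5)
cohort = cw.generate_cohort(params)

section = cw.run_early_cc_analysis(
    cohort, cw.AnalysisConfig(cutoff_mode="youden"))

print(f"excluded (relapse within 60 d): "
      f"{section['n_excluded_early_relapse']}")
print(f"derived CC cutoff:  {section['cutoff_used']:.3f}% recipient")
print(f"groups:             CC n={section['n_cc']}, MC n={section['n_mc']}")
km = section["km"]
cc, mc = km["CC"], km["MC"]
print(f"2-year relapse-free survival, CC: "
      f"{100 * cc['survival_at_horizon']:.0f}% "
      f"(95% CI {100 * cc['ci_at_horizon'][0]:.0f}-"
      f"{100 * cc['ci_at_horizon'][1]:.0f}) [design 90%]")
print(f"2-year relapse-free survival, MC: "
      f"{100 * mc['survival_at_horizon']:.0f}% "
      f"(95% CI {100 * mc['ci_at_horizon'][0]:.0f}-"
      f"{100 * mc['ci_at_horizon'][1]:.0f}) [design 65%]")
print(f"log-rank p = {km['logrank_p']:.2g}")
print()
print("Transplants that reach complete donor chimerism (at least one "
      "blood CD3+ value below the cutoff within 60 days) have a "
      "markedly higher probability of remaining relapse-free; the KM "
      "estimates recover the designed group contrast.")
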