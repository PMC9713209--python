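"""Generate a synthetic post-HSCT chimerism cohort and describe it.

The generator emulates the data structure of lineage-specific
chimerism monitoring after transplantation for B-ALL: ~20% relapse
probability, log-normal relapse times (median 264 days), irregular
clinician-driven sampling, engraftment-phase mixed chimerism decaying
toward complete donor chimerism, and a pre-relapse T cell chimerism
rise.
"""

import chimwatch as cw

params = cw.default_params(seed=7)
cohort = cw.generate_cohort(params)

n = cohort.n_transplants
relapsed = cohort.transplants["relapse_day"].dropna().astype(float)
print(f"transplants:            {n}")
print(f"measurements:           {len(cohort.measurements)}")
print(f"pediatric transplants:  {(cohort.age_group() == 'pediatric').sum()}")
print(f"relapses observed:      {len(relapsed)} "
      f"({100 * len(relapsed) / n:.1f}%)")
print(f"median relapse day:     {relapsed.median():.0f}")

pairs = cw.paired_samples(cohort, "CD3")
corr = cw.paired_correlation(pairs)
print(f"paired blood/marrow CD3 samples: {corr.n}, Pearson r = {corr.r:.2f}")
print()
print("The relapse fraction and relapse timing follow the configured "
      "cohort structure; the paired-sample correlation is high but "
      "imperfect, reflecting the additive marrow-blood discordance and "
      "measurement noise in the trajectory model.")
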