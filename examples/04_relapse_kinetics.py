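"""Chimerism kinetics in the months before relapse.

Pools all measurements of relapsed transplants with time re-indexed so
relapse is day 0 and fits LOESS curves per cell type: the leukemia
lineage (CD19+ for B-ALL) surges at relapse, while T cell (CD3+)
chimerism shows a smaller transient rise months earlier.
"""

import numpy as np

import chimwatch as cw

params = cw.default_params(seed=13)
params.n_transplants = 400
cohort = cw.generate_cohort(params)

section = cw.run_kinetics(cohort, disease_lineage="CD19")
print(f"relapsed transplants: {section['n_relapsed']}")
for key in ("marrow_CD3", "marrow_CD19"):
    curve = section["curves"][key]
    grid = np.array(curve["grid"])
    fitted = np.array(curve["fitted"])
    window = (grid >= -180) & (grid <= -30)
    print(f"{key}: n = {curve['n_points']} points")
    print(f"  fitted level one year out:        "
          f"{fitted[grid <= -300].mean():6.2f}% recipient")
    print(f"  fitted peak in [-180, -30] days:  "
          f"{fitted[window].max():6.2f}% recipient")
    print(f"  fitted value at relapse (day 0):  {fitted[-1]:6.2f}% recipient")
print()
print("The CD19+ curve stays low until it surges at relapse (the MRD-like "
      "signal), whereas the CD3+ curve rises transiently months before "
      "relapse -- the early-warning pattern the landmark %max analysis "
      "exploits.")
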