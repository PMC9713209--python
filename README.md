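# chimwatch

Lineage-specific donor–recipient chimerism analysis for relapse
prediction after allogeneic hematopoietic stem cell transplantation
(HSCT).

## The problem

After an allogeneic HSCT for acute leukemia, the fraction of DNA in a
blood or bone marrow sample that still originates from the *recipient*
("percent recipient chimerism", 0% = complete donor chimerism) is
monitored routinely — overall and in immunomagnetically enriched cell
subsets (CD3⁺ T cells, CD19⁺ B cells, CD33⁺ myeloid cells, CD34⁺
progenitors). Rising recipient chimerism can precede a hematological
relapse by months, which matters clinically because immune
interventions (tapering immunosuppression, donor lymphocyte infusion)
work best early. chimwatch implements two complementary
chimerism-based strategies for relapse risk assessment, plus
everything needed to exercise them end to end on synthetic cohorts:

1. **Landmark %max prediction.** Measurements are filtered to a
   landmark window — at least 30 days after HSCT (to exclude
   engraftment-phase mixed chimerism) and at least 30 days before the
   relapse (or, for non-relapsed transplants, before the relapse
   group's average relapse day, so observation time is comparable).
   The highest retained value per transplant,

   %max = max{ percent recipient : 30 ≤ day ≤ relapse_day − 30 },

   is evaluated as a relapse predictor by univariable and
   multivariable logistic regression and by ROC analysis, with the
   operating cutoff chosen by Youden's J = sensitivity + specificity − 1.

2. **Early complete-chimerism (%min) stratification.** %min is the
   lowest value in the first 60 days after HSCT (blood). A transplant
   achieves early complete chimerism (CC) when %min falls strictly
   below a small cutoff; CC vs mixed chimerism (MC) groups are then
   compared by Kaplan–Meier relapse-free survival and the log-rank
   test, with 2-year estimates and Greenwood confidence intervals.

All supporting statistics — ROC/AUC with Youden cutoff selection,
logistic regression by iteratively reweighted least squares with Wald
intervals, the Kaplan–Meier product-limit estimator with Greenwood
variance, the log-rank test, Fisher's exact test, the chi-square test,
the Mann–Whitney U test, Pearson correlation and LOESS smoothing — are
implemented from first principles in `chimwatch.stats` and verified
against brute-force oracles and established libraries in the test
suite.

Because no patient-level cohort is distributed, the package ships a
synthetic cohort generator (`chimwatch.simulate`) that emulates the
structure such data has: ~20% relapse fraction with log-normal relapse
times (median 264 days), clinician-driven irregular sampling,
engraftment-phase chimerism decay, blood/marrow discordance,
measurement noise with a detection limit, a transient pre-relapse CD3⁺
rise and a terminal leukemia-lineage surge, and an optional link
between failed early donor-chimerism clearance and relapse risk.

## Worked example

```python
import chimwatch as cw

params = cw.default_params(seed=7)
params.n_transplants = 600
cohort = cw.generate_cohort(params)

section = cw.run_maxchim_analysis(cohort, cw.AnalysisConfig(
    age_group="all", compartment="marrow", lineage="CD3"))
roc = section["roc"]
print(f"AUC (%max, marrow CD3): {roc['auc']:.2f}")
print(f"Youden-optimal cutoff:  {roc['youden_cutoff']:.2f}% recipient")
print(f"sensitivity:            {100 * roc['sensitivity']:.0f}%")
print(f"specificity:            {100 * roc['specificity']:.0f}%")
```

prints

```
AUC (%max, marrow CD3): 0.87
Youden-optimal cutoff:  1.28% recipient
sensitivity:            78%
specificity:            89%
```

meaning: on this simulated 600-transplant cohort, the maximal landmark
CD3⁺ bone marrow chimerism discriminates future relapses from
non-relapses with AUC 0.87, and calling "elevated risk" whenever a
single value reaches 1.28% recipient catches 78% of relapses while
correctly clearing 89% of non-relapsing transplants. The
`examples/` directory contains this and three further narrative
scripts (cohort simulation and description, early-CC stratification
with a designed 90% vs 65% two-year contrast, and pre-relapse
chimerism kinetics), each printing the numbers it computes and a line
on what they mean.

A thin CLI wraps the same functions:

```sh
chimwatch simulate --n 138 --seed 7 --out-dir cohort/
chimwatch maxchim --transplants cohort/transplants.tsv \
    --measurements cohort/measurements.tsv --compartment marrow \
    --lineage CD3 --age-group all --out maxchim.json
chimwatch run --transplants cohort/transplants.tsv \
    --measurements cohort/measurements.tsv --out-dir report/
```

## Layout

| Module | Contents |
| --- | --- |
| `chimwatch.cohort` | data model, TSV/CSV I/O, validation, paired blood–marrow samples |
| `chimwatch.simulate` | synthetic longitudinal cohort generator |
| `chimwatch.landmark` | landmark filtration, %max, relapse-day snapshot |
| `chimwatch.earlycc` | %min, early-relapse exclusion, CC/MC dichotomization, cutoff presets |
| `chimwatch.stats` | ROC/Youden, logistic IRLS, Kaplan–Meier, log-rank, Fisher, χ², Mann–Whitney, LOESS, Pearson |
| `chimwatch.pipeline` | orchestration, report serialization |
| `chimwatch.cli` | `chimwatch` command (simulate / maxchim / earlycc / kinetics / run) |

See `docs/methods.md` for the model, parameter and design
documentation.
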