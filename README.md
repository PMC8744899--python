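# arealsurv

Bayesian spatial survival analysis for under-five child mortality with
county-level ICAR frailties.

Demographic and Health Survey birth histories record, for each child born in
the five years before interview, a follow-up time in months (0–60) and
whether the child died — heavily right-censored survival data with strong
geographic structure. `arealsurv` is for epidemiologists and biostatisticians
who want to ask: *after adjusting for the usual demographic and
socio-economic risk factors, how much of the remaining variation in the
hazard of death is spatial, and which areas carry it?*

## Model

Child *i* in area *a(i)* has hazard

```
h_i(t) = h0(t) · exp( x_i'β + w_a(i) )
```

* `h0(t)` — piecewise-constant baseline hazard on (0, 60] months,
* `β` — log hazard ratios for the covariate set (child sex, residence,
  household-head sex, wealth quintile, maternal education, mother's ages at
  first and at this birth, twin status),
* `w` — area frailties with an intrinsic CAR (ICAR) prior on the county
  contiguity graph, variance `σ²`, identified by a sum-to-zero constraint.

Posteriors come from a Metropolis-within-Gibbs sampler (conjugate
inverse-gamma Gibbs step for `σ²`, plus an interweaving rescale that keeps
the variance mixing honest). The spatial model is compared against the
no-frailty proportional-hazards model by DIC, WAIC and LPML; fit is checked
with Cox–Snell residuals; effects are reported as hazard ratios with 95%
credible intervals; frailties export as a per-county table or GeoJSON
choropleth. A synthetic-data generator emulates the KDHS-like structure (47
counties, interview-age censoring, realistic covariate marginals and effect
sizes) so the whole pipeline runs with known ground truth and no gated data.
See `docs/methods.md` for the full model, priors and design choices.

## Worked example: hazard-ratio report

The package ships the published posterior coefficient summaries for the
KDHS-2014 spatial Cox analysis as its reference effect table (they are also
the generator's default true coefficients). The effect report exponentiates
means and interval endpoints and quotes protective effects as a percent
survival gain:

```python
from arealsurv import hazard_ratio_report
from arealsurv.report import format_effect_table
from arealsurv.synthetic import reference_effect_table

report = format_effect_table(hazard_ratio_report(reference_effect_table()))
print(report[["mean", "hazard_ratio", "hr_ci_low", "hr_ci_high",
              "percent_reported", "direction"]])
```

```
                                          mean  hazard_ratio  hr_ci_low  hr_ci_high  percent_reported direction
Sex of the child (Female)              -0.1304        0.8777     0.7761      0.9921             12.23  decrease
Sex of household head (Female)         -0.1550        0.8564     0.7548      0.9842             14.36  decrease
Highest Level of Education (Secondary) -0.2982        0.7422     0.5750      0.9873             25.78  decrease
Age of respondent at first birth        0.0251        1.0250     1.0040      1.0470              2.54  increase
Child is twin (2nd Multiple)            0.4438        1.5590     1.1000      2.1350             55.86  increase
...
```

Read: female children face a hazard ratio of 0.88 (a 12.2% survival
advantage over male children); a second set of twins carries a 56% higher
hazard than a singleton; each year of the mother's age at first birth adds
~2.5% to the hazard.

## Worked example: simulate, fit, compare

```sh
arealsurv simulate --out data --seed 1 --n-areas 10 --children-per-area 60
# wrote 590 records (29 events) to data
arealsurv fit --records data/records.csv --adjacency data/adjacency.txt \
    --iterations 3000 --burn-in 1000 --thinning 2 --seed 1 --out chains
arealsurv fit --records data/records.csv --no-spatial \
    --iterations 3000 --burn-in 1000 --thinning 2 --seed 1 --out chains_ns
arealsurv compare chains chains_ns --out comparison.csv
```

```
                  DIC         pD        LPML        WAIC      pWAIC
chains     426.020449  15.316692 -221.973591  441.606554  27.813606
chains_ns  432.296655  18.750251 -222.015941  442.490681  26.018231
```

The spatial model (`chains`) attains the lower DIC and WAIC and the higher
LPML on this dataset, which was generated with true frailty variance 0.2 —
the expected ordering when spatial heterogeneity is real. `arealsurv
diagnose` adds trace/ESS/Geweke summaries and the Cox–Snell residual curve;
`arealsurv map` exports per-county posterior median frailties; `arealsurv
pipeline --config cfg.yaml --out run/` does all of the above in one shot.
Custom adjacency can be supplied as a two-column edge list or a GAL
spatial-weights file.

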