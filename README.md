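# gallop

Exercise-history workload analytics and matched case-control modelling for
Thoroughbred racehorse careers.

Condylar fractures of the third metacarpal/metatarsal bone are a leading
musculoskeletal injury in racing Thoroughbreds, and fractures located in the
parasagittal groove (PSG) of the condyle appear to arise from a different
training history than fractures abaxial to the groove (non-PSG).  Testing
that hypothesis requires reducing each horse's lifetime record of races and
official timed works to a panel of workload variables, comparing fracture
groups, and contrasting each case with matched controls drawn from the same
last event.  `gallop` implements that entire analysis as a reusable,
seed-deterministic pipeline for epidemiologists and equine-sports
researchers, with a synthetic career generator standing in for proprietary
past-performance records.

## What it computes

**Workload panel.** Each career is truncated at an *index date* (fracture
date for cases, matched-event date for controls) and segmented: any gap of
more than 60 days between consecutive events is a *layup*, the rest is the
*active* career.  From the truncated timeline ~55 variables are derived —
counts and furlongs (F) of races, works and events; mean inter-event
intervals (career and active); layup counts, durations and percent of
career; rates per year and F/month; windowed distances in the 1–12 months
before the index date and after the first career event; and OLS slopes of
the cumulative-furlong curve (F/month) at career start, after the last
layup, and just before the index date.

**Matched design.** Every case is matched to 3 controls that took part in
its last event before fracture, of the same sex and foal crop (birth year).
For a 1:m stratum with covariates x and coefficient vector β, the
conditional likelihood contribution is

```
P(case | stratum) = exp(x_case·β) / Σ_j exp(x_j·β)
```

which removes stratum-level nuisance effects ("racehorse class").

**Statistical battery.** Two-sided Wilcoxon rank-sum tests (exact
enumeration when both groups have ≤ 10 values), Pearson chi-square with
optional Yates correction, Fisher's exact test, exact post-hoc power for a
two-proportion Fisher comparison by full enumeration of the binomial
outcome grid, simple and conditional logistic regression with Wald ORs and
95% CIs, Box–Tidwell linearity checks with quartile categorisation of
non-linear covariates, stepwise/backward AIC model selection (univariable
p < 0.20 screen; age and sex always candidates), and Hosmer–Lemeshow plus
ROC-AUC diagnostics.

## Worked example

Simulate a full study (40 PSG-like + 40 non-PSG-like cases, 1:3 matched
control pools) and run every stage:

```bash
gallop run --out results/demo --seed 42
```

This writes `variables.csv`, `group_comparison.csv`, `strata.csv`,
univariable and final-model tables per group, `outcome.json`, career plots,
and a `summary.json`.  Selected output from that exact command:

| variable            | median non-PSG | median PSG | Wilcoxon p |
|---------------------|---------------:|-----------:|-----------:|
| races_per_year      | 7.11           | 2.99       | <0.001     |
| n_layups            | 0              | 1          | 0.003      |
| pct_career_in_layup | 0.0            | 18.1       | 0.011      |
| dist_before_6m_f    | 72.2           | 53.8       | <0.001     |
| active_days         | 335            | 330        | 0.42       |

The non-PSG phenotype races more than twice as often with almost no layup
time, while the PSG phenotype spends ~18% of its career in layup — the
planted contrast the generator encodes.  The matched non-PSG model at this
seed retains `active_work_rate_f_per_month` (OR 0.25), `age_years`
(OR 0.30), `between_events_active_days` (OR 0.36) and `dist_before_1m_f`
(OR 0.87) with AUC 0.83 and Hosmer–Lemeshow p = 0.48; the outcome stage
reports 65.0% vs 55.0% return to racing (chi-square p = 0.36, exact Fisher
power 0.11).

Each stage is also available separately (`gallop simulate | extract |
match | compare | casecontrol | outcome | plot`) and as library functions
(`gallop.pipeline`, `gallop.stats`, ...).

## Layout

```
src/gallop/
  events.py    # domain records, validation, CSV I/O, career truncation
  metrics.py   # layup segmentation + the workload-variable panel
  matching.py  # 1:3 matched case-control set construction
  simulate.py  # synthetic careers, presets, full study bundles
  stats.py     # the statistical battery
  pipeline.py  # study orchestration and reports
  cli.py       # command-line interface
```
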