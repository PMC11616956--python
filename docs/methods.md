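# Methods

This note records the modelling conventions, defaults, and design choices
behind `gallop`, and what the synthetic generator does and does not
emulate.

## Careers, truncation and segmentation

A career is the dated sequence of high-speed events — races and official
timed works — from the first recorded event to the index date.  Dates are
whole calendar days; every duration is an integer day difference.  The
index date is the fracture date for cases and the matched event's date for
controls.  Events dated exactly on the index date are retained by default
(`AnalysisConfig.include_index_day_event`): fractures occur during an
event, so the precipitating event is normally the last record of the
career.  Strict exclusion is available behind the flag.

A *layup* is a gap of strictly more than `layup_threshold_days` (default
60) between consecutive events.  The layup's duration is the full day gap
between the bounding events — the definition names the whole period
without a race or work, not the excess over the threshold.  The trailing
gap from the last event to the index date is never a layup: a case's index
follows its last event closely, and a control's index *is* an event.
Conservation (`active_days + layup_time_days = career_length_days`) holds
by construction and is property-tested.

For horses with no layup, time-since-last-layup is the whole career
(index minus first event) and events-since-last-layup is the total event
count; per-horse mean layup duration is 0.  This keeps the variables
defined for every horse, which the group-level reporting relies on.

## The workload panel

All ~55 variables are derived deterministically from the truncated
timeline.  Conventions:

* **Calendar constants.** Month = 30.4375 days, year = 365.25 days
  (configurable).  Rates are `count / (days / 365.25)` per year and
  `furlongs / (days / 30.4375)` per month; *active* variants substitute
  active days for career days.
* **Windowed distances.** `dist_before_<h>m` sums event furlongs in the
  half-open window `(index − h·month, index]`, so an index-day event
  counts at every horizon; `dist_after_first_<h>m` uses
  `[first, first + h·month)`.  The derived month buckets are exact
  differences of these windows (month 2 = horizon 2 − horizon 1, months
  3–4 = horizon 4 − horizon 2, months 5–6 = horizon 6 − horizon 4, month
  1 − month 2 = horizon 1 − bucket 2), so the identity chain holds to the
  bit.
* **Slopes.** Workload intensity is the OLS slope of the cumulative
  furlong step curve against time in months, over events inside a 60-day
  window: ending at the index date (slope at fracture), starting at the
  first event (slope at start), and starting at the event that closes the
  last layup (slope after last layup).  The window length is a
  configurable default; at least two event dates must fall inside the
  window, otherwise the slope is missing.
* **Missingness.** A variable is `None` exactly when its denominator or
  prerequisite is absent: inter-race intervals need ≥ 2 races, per-race
  distance needs ≥ 1 race, active rates need active days > 0, percent of
  career in layup needs a career longer than zero days.
* **Active inter-event intervals.** Each consecutive-event gap has any
  overlapping layup days subtracted before averaging; a gap that is
  itself a layup therefore contributes zero.
* **Age.** `age_years` defaults to ⌊age_days / 365.25⌋; the North
  American January-1 racing age is available behind
  `AnalysisConfig.racing_age`.

## Matching

Controls must share the case's last event before fracture, its sex
(female/male; geldings and colts are male) and its foal crop (same birth
year — racing cohorts are year-based, and no tighter tolerance is
defined).  Event identity is calendar date plus event type, the natural
contract in the synthetic world where a shared event is constructed
explicitly.  When more than k candidates are eligible, a uniform seeded
draw without replacement selects k; fewer than k is a reported failure
naming the stratum and the shortfall.  A control may serve several
strata; the conditional-likelihood analysis nevertheless treats strata as
independent, a documented limitation of the design.

## Statistical battery

* **Wilcoxon rank-sum.** Two-sided throughout.  When both groups have at
  most 10 observations the p-value is exact: a subset-sum dynamic
  program over the tie-averaged pooled ranks counts, among all C(n, n1)
  group assignments, those whose rank-sum deviates from its expectation
  at least as much as observed — identical to exhaustive enumeration but
  polynomial-time.  Larger samples use the tie-corrected normal
  approximation with continuity correction.  The approximation is not
  relied on at small n; at pooled n = 8 its worst-case deviation from
  exact enumeration is large at extreme splits because the exact null
  distribution is coarse, which is why the exact branch exists.
* **Contingency tests.** Pearson chi-square (Yates correction optional,
  2×2 only); Fisher's exact test with the standard two-sided rule (sum
  of all outcome probabilities not exceeding the observed table's).
  A zero marginal yields p = 1 by convention, flagged.
* **Exact post-hoc power.** For two independent proportions, enumerate
  the (n1+1) × (n2+1) grid of binomial outcomes under the true
  proportions and sum the probability of the two-sided Fisher rejection
  region at α.  The Fisher p-values are computed per first-column total
  from the hypergeometric pmf, which makes the enumeration exact and
  fast.
* **Logistic models.** Simple logistic regression is maximum likelihood
  with Wald inference; conditional logistic regression maximises the
  product over strata of `exp(x_case·β)/Σ_j exp(x_j·β)`.
  Stratum-constant covariates are dropped as uninformative; a covariate
  constant within every stratum is an error.  Perfect separation and
  singular information matrices are detected and raised as errors naming
  the covariate where one is identifiable.  ORs are `exp(β)` with Wald
  95% CIs; the global test is the likelihood ratio against the null
  model; AIC = 2k − 2ℓ.
* **Linearity and categorisation.** Box–Tidwell augments the model with
  `x·ln(x)` and reads the Wald p of the augmentation term; zeros are
  shifted by +1 first, negatives are an error.  Covariates failing the
  check are recoded into four quartile bands at the empirical 25/50/75%
  cutpoints (linear interpolation); assignment is left-closed (a value
  equal to a cutpoint falls in the lower band) and the lowest band is the
  reference.
* **Selection.** Candidates are screened by univariable Wald p < 0.20;
  age and sex remain candidates regardless.  `stepwise` alternates
  add/drop moves from the intercept-only model, `backward` only drops
  from the full screened model; the move that lowers AIC most wins and
  ties break on covariate name, making the search reproducible.
* **Diagnostics.** Hosmer–Lemeshow uses quantile groups of fitted
  probability (default 10) with groups − 2 df; too few distinct fitted
  values, duplicate quantile edges, or a zero expected count are errors
  suggesting fewer groups.  AUC is the concordance probability with ties
  counted one half.
* Significance is read at 0.05, two-sided, with no multiple-testing
  correction — the analysis battery intentionally mirrors a screening
  design that applies none across its ~60 group comparisons.

## Outcome analysis

A case *returned* if it has at least one race after its repair date.
Earnings are positive when race earnings in the 365 days following the
return race exceed earnings in the 365 days before fracture; both windows
are closed at day 365.  The alternative anchor (365 days following
repair) sits behind `earnings_anchor="repair"` since the two phrasings of
the window are not perfectly aligned in common usage.  Group contrasts
use the plain (uncorrected) chi-square test plus the exact Fisher power
at the observed proportions.  Cases without a repair date are excluded
and logged.

## Synthetic careers

The generator reproduces *exposure structure*, not injury biology: a
backbone of timed works with log-normal inter-work gaps (median ≈ 2
weeks), races inserted inside active inter-work gaps at a per-year rate,
layups injected by a hazard per active year with log-normal durations
forced above 60 days, and distances drawn from truncated normals recorded
to the nearest half furlong (works ≈ 4 F, races ≈ 6–7 F).  Log-normal
gaps and durations give the right-skewed mean ≫ median pattern real
layup data show.  Presets pin group *medians*: the non-PSG-like phenotype
races often (≈ 8/yr) with rare layups, the PSG-like phenotype races less
(≈ 4.7/yr), works at slightly longer intervals and spends ≈ 27% of its
career in layup; controls sit between.  Each preset exposes the medians
it is designed to produce (`CareerParams.targets()`), and the
generator/extractor round trip is tested at n = 500 with stated
tolerances: ±1.5 days on the median active between-works interval, ±15%
on active works per year, ±5 percentage points on percent of career in
layup.

A full study bundle anchors each case's last event at a random date in a
three-year window, sets the fracture 0–21 days after that event and the
repair 1–10 days later, and constructs per-case control pools that share
the last event, sex and foal year *by construction*, so 1:3 matching
never fails on synthetic data.  Post-repair racing (for the outcome
stage) occurs with a preset probability after a 150–320 day convalescence,
at the phenotype's racing rate.

What the generator does **not** model: track, surface, trainer and class
covariates; seasonal scheduling; wastage and censoring other than the
index truncation; any biomechanical injury mechanism.  Passing tests
therefore demonstrate that the pipeline recovers structure the generator
plants, not that real careers satisfy the same contrasts.

## Determinism and problem sizes

Every stochastic step takes a seed; the pipeline fans a master seed out
to per-stage seeds via `numpy.random.SeedSequence`, logged in the report
header, and fixed seeds give byte-identical CSV/JSON bundles.  The test
suite exercises segmentation invariants on 1,000 generated careers,
parameter recovery at n = 500 per preset, planted-difference detection
over 50 replicates of 40 + 40 careers, and end-to-end determinism on a
6 + 6 study — sizes chosen to keep the default suite fast while leaving
the estimators comfortably in their asymptotic regime.

## Known limitations

* The matched sets reuse controls across strata without any correction.
* The conditional and simple logistic screens share one candidate list;
  variables inestimable in one family are reported as missing there
  rather than re-derived.
* The slope windows (60 days) are a package default; other window
  choices change the intensity variables and are exposed in the config.
* Quartile cutpoints use linear interpolation between order statistics;
  packages using other quantile rules will place boundary values
  differently.
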