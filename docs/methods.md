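# Methods

`adscreensim` is an individual-level Monte Carlo microsimulation of
presymptomatic Alzheimer-disease (AD) screen-and-treat strategies. It answers
one question: under what combinations of screening accuracy, treatment
efficacy, treatment harm and adherence does a one-time screen at a given base
age, followed by lifelong preventive treatment of screen-positives, deliver a
positive aggregate net benefit, measured in discounted quality-adjusted life
years (QALYs) per 1000 screened or per 1000 treated?

## Model structure

### Untreated-world life histories

A cohort of `population_size` AD-free adults enters at a common base age
(55–75 in 5-year steps). Each individual receives:

* **Sex** — Bernoulli draw from a base-age-specific proportion-female table.
* **Non-AD death age** — sampled year by year from a sex-specific annual life
  table: one uniform per year of possible life from the base age to 120; the
  individual dies in the first year whose draw falls below that year's death
  probability `q(age, sex)`. The life table's terminal row has `q = 1`, so
  death is forced by the age cap of 120.
* **Conversion risk score** — a single uniform in [0, 1] that determines
  *priority* of AD conversion, not its probability.
* **Destined AD onset age** — assigned by an annual quota: for each year, the
  expected number of new conversions is `rate(age) x (not-yet-converted
  count)`, rounded to the nearest integer with the fractional remainder
  carried into the next year (so long-run totals are unbiased); that many
  individuals are taken from the not-yet-converted members with the highest
  risk scores. By default the quota denominator is the *original* cohort and
  conversions may be assigned to individuals who are already dead; such
  **censored conversions** are recorded but contribute no downstream disease,
  utility or benefit. The alternative, restricting quotas and draws to the
  living, is available via `quota_risk_set="alive"`.

The annual AD incidence follows an exponential age model: it doubles every
`doubling_time` years above age 60 and halves every 5 years below 60,
anchored at `lambda60`, clipped to [0, 1]. The defaults (`lambda60 = 0.001`
per year, `doubling_time = 5.0` years) sit in the range the epidemiological
literature reports for AD incidence near age 60 and its age-doubling; they
imply a 20-year destined conversion probability of about 5.7% from age 55 and
about 60% from age 75. Because no canonical coefficient pair exists, both
live in the run configuration as data, not code.

### The AD course (Markov model)

At onset an individual draws an initial severity (mild 0.6, moderate 0.4) and
starts in the community. Each subsequent year applies, in order: the
severity transition (mild/moderate/severe/dead, from the severity-specific
row), then — for survivors — the community-to-nursing-home transition at the
new severity. Severity never improves and the nursing home is absorbing
(hierarchical structure). Mortality with AD is governed solely by the
transition rows; the pre-drawn life-table death age is discarded at onset.
The published moderate row sums to 0.957; rows are renormalized
proportionally at construction (logged), rather than assigning the deficit to
any one cell. AD mortality depends on severity only: the model's death
probabilities are printed at severity level, so location affects utility, not
mortality.

Utilities: non-AD years take age-band values (0.872 / 0.836 / 0.809 / 0.775
for 55–64 / 65–74 / 75–84 / 85+); AD years take severity x location values
(mild 0.37 community / 0.52 nursing home; moderate 0.18 / 0.21; severe
0.02 / 0). Accrual is annual with no half-cycle correction: the onset year
accrues at the initial severity in the community, a death year accrues
nothing. All utilities are discounted as `(1 - rate)^(age - base_age)` with
rate 0.03 — note this is the model's own convention, not `1/(1+r)^t`; 35
years out the weight is 0.97^35 ~ 0.34.

### Screening

A single screen at the base age targets conversion within a 20-year horizon
(inclusive boundary). Within-horizon converters screen positive with
probability `sensitivity` (0.65), everyone else with `1 - specificity`
(specificity 0.95). By default "converter" means *destined* to convert within
the horizon whether or not death intervenes — the pre-test 20-year risk is an
incidence quantity with no mortality adjustment, so a destined converter who
dies early is still the screen's target condition. The stricter reading
(onset must precede death) is available via
`count_censored_conversions=False`. Censored-conversion "true positives" are
treated, can be harmed, and can never benefit.

### Treatment

Both true and false positives start treatment at the base age. Efficacy is a
relative risk reduction growing linearly with lead time,
`RRR = min(slope x years_to_onset, ceiling)` (base slope 0.03/year, ceiling
0.5, reached at 17 years of lead time). Each treated year carries independent
probabilities of a harm event (0.001/year; a one-time 0.06-QALY decrement
discounted at the harm year, after which treatment stops permanently) and of
non-harm discontinuation (0.05/year; harm is checked first within a year).
Annual event years are realized by inverse-transform of the geometric
distribution from per-individual stored uniforms, which makes every
sensitivity curve a common-random-number pairing: raising the harm
probability can only move a given individual's harm year earlier.

Prevention is **all-or-nothing at the destined onset year**: if the
individual is still on treatment when the destined onset arrives, the onset
is cancelled with probability `RRR(lead time)`, and the individual follows
the untreated non-AD life course to the pre-drawn life-table death age
(common-random-number counterfactual; no immortal-cohort bias). A cancelled
individual is not re-exposed to conversion risk. This is the central
modeling choice: we evaluated a re-exposure variant (cancelled onsets
re-drawn annually from ongoing incidence, with re-cancellation requiring
continued treatment) and found it changes net benefit by under 10% at
younger base ages, at the cost of substantial extra machinery, so the simpler
mechanism is kept (`TreatmentParams.prevention_mode` is the hook for
alternatives). Harm decrements are discounted, consistent with all other
utilities, and are not capped by remaining life-years.

### Net benefit and trials

Net utility per individual is the treated-world minus untreated-world
discounted QALY total under common random numbers; it is exactly the
cancelled-onset benefit (non-AD tail minus AD-path tail) minus any harm
decrement, and exactly zero for a null treatment. The Monte Carlo study
samples `n_trials` trials of `trial_size` individuals (default 1000 x 1000)
without replacement within a trial (Floyd's algorithm), independently across
trials, and reports the mean and SD of per-trial net utility scaled to per
1000 screened. Per-1000-treated values are defined as
`per_screened x 1000 / mean_treated`, so the tabulated identity holds
exactly. Under treat-all, a "false positive" is any treated non-converter.

## Sensitivity analyses

* **One-way**: each primary parameter swept over its published range, all
  else at base case, same cohort and uniforms at every grid point (paired
  curves). Sweeping the discount rate re-derives the QALY decomposition;
  sweeping the base age rebuilds the cohort with the same seed.
* **Two-way**: harm probability x harm magnitude grid, same pairing.
* **Multi-way (3rd-order Monte Carlo)**: every uncertain parameter redrawn
  per iteration — intervention and diagnostic parameters uniform over their
  one-way ranges; non-AD utilities uniform over their published ranges; AD
  utilities perturbed additively by ±0.1 (clamped to [0, 1]); transition,
  initial-severity and nursing-home probabilities perturbed by ±10% relative
  and renormalized. The population structure carries no sampled uncertainty,
  so one 100,000-person cohort at base age 55 is shared across iterations,
  with AD courses re-simulated from a fixed path seed (common random
  numbers). The reduced per-iteration design is 100 trials x 1000
  individuals sampled with replacement across pooled trials (collisions are
  negligible at that scale); `PSASpec(full_design=True)` switches to 1000
  trials. The per-iteration efficacy summary ("realized mean RRR") is the
  mean `RRR(lead)` across treated destined converters; the expressed-only
  variant and the raw slope/ceiling draws are recorded alongside so the
  definition is auditable.

## Reproducibility and numerics

All randomness derives from one integer seed through a fixed spawn order of
`numpy` `SeedSequence` children (sex, death, risk, AD paths, per-individual
classification/harm/discontinuation/cancellation uniforms, trials). Storing
the four behavioral uniforms per individual is what makes strategies and
parameter settings comparable draw-for-draw: the untreated world of a trial
is bit-identical across strategies. Risk-score ties break by id; quota
rounding is round-half-away-from-zero with carry; event ties within a year
resolve harm before discontinuation, and death checks precede onset checks.

## What the synthetic data do and do not show

The packaged life table and sex proportions are smooth Gompertz / census-style
approximations to the corresponding US tables (labelled synthetic in their
filenames); the toy fixtures from `make_toy_fixtures` are smaller still.
They reproduce realistic life expectancy (about 23.7 / 27.1 years at 55 for
men / women) and the exponential age-structure of AD incidence, which is what
the model's conclusions rest on. They do not model cohort trends, risk-factor
covariates (education, vascular risk, activity), heterogeneity in progression
speed, treatment effects on progression, repeat screening, or costs — so
passing tests demonstrate internal consistency and calibration to the tables
supplied, not forecasts for any particular real population.

## Problem sizes used by the test suite

The acceptance-style tests run the full 10^6-person cohort with 1000 x 1000
trials per base age for the outcome table, a 10^6 cohort for population
calibration, 10^5 Markov paths for the absorbing-chain comparison, 10^5-person
cohorts for the sensitivity sweeps, and 2000 PSA iterations on a shared
10^5-person cohort; the whole suite completes in a couple of minutes on one
CPU. The full 10,000-iteration PSA is available through `PSASpec` or
`adscreensim psa --iterations 10000`.

## Known limitations

* The incidence coefficients are calibration data with no single canonical
  source; absolute benefit levels (not signs, orderings or monotonicities)
  shift with them.
* Benefit magnitudes at the youngest base ages are the quantity most
  sensitive to the all-or-nothing prevention choice and to how adherence
  interacts with long lead times; the per-treated benefit at age 55 should be
  read as scenario-dependent.
* One-year cycles and integer ages throughout; no within-year event timing.
* No costs: the model measures net QALYs only, not cost-effectiveness.
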