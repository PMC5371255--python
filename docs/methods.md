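# Methods

## Model structure

The package models a five-year rollout of paraprofessional-delivered group
CBT for alcohol reduction to HIV+ outpatients at 12 Kenyan sites, from a
societal perspective in constant 2013 USD.

**Costing** is ingredient-based: every cost is a line item
(units × unit cost, KES) in one of two ledgers. The training ledger
(KES 4,369,168 ≈ $51,688) is incurred once, in year 1; the per-site ledger
(KES 752,555 ≈ $8,903/site-year) recurs for each of the 12 sites in each of
the five cost years, with no real cost growth (constant-dollar framing).
A single exchange rate, 84.53 KES/USD, is applied to all years; USD figures
are rounded only for reporting.

**Enrollment** follows the 160/240 schedule: each site serves 160
participants in year 1 (two counselors, two groups/week) and 240 in years
2–5 (three groups/week), totalling 12 × (160 + 4 × 240) = 13,440. An
alternative figure of 320 participants/site for years 2–5 circulates with
this program design, but only 240 is consistent with the 13,440 total and
with the per-site ledger's participant-payment line; the schedule is a
config value, so the 320 variant can be run if wanted.

**Benefits** are valued per person-year and gated by the abstinence-rate
difference Δ = 0.69 − 0.38 = 0.31. The 90-day abstinence difference is
treated as the probability of sustained abstinence over each benefit year —
the interpretation the per-person-year arithmetic requires.

* Averted HIV incidence: Δ × 0.13 (alcohol-attributable fraction of new
  infections, consumed as an input, not re-derived from transmission
  modelling) × the annual per-patient HIV treatment cost. The treatment
  cost sums four 2009-USD non-drug components (lab 32, visits 24, support
  services 0.4, fixed 32) inflated by CPI 140.103/100 to 2013 (≈$123.85,
  reported as 124) plus the 2013 ARV drug cost 145.47, ≈$269.32 in total.
  The attributable fraction is applied as an expected rate; no
  individual-level transmission events are modelled.
* Productivity: Δ × a × (w_LFP + ½·w_HP), with a = 19/69 − 112/1439
  (≈0.19753, carried at full precision; printed as 19.75%). Labor-force
  participation is valued for both sexes as a proportional rise in annual
  minimum-wage income: 0.19 × $76.93 × 12 ≈ $175.40/year. Household
  production is valued for the female half only: (1.056 + 1.945) weekly
  hours × $0.85/h × 48 weeks ≈ $122.44/year.

**Annualization conventions.** The source tables never state the
hours→money conversion for the productivity benefits. Among the candidate
conventions ({proportional wage rise vs hourly valuation of LFP hours} ×
{48 vs 52 weeks of household production}), only the proportional-wage-rise
LFP rule with 48-week household annualization reproduces both the printed
per-person-year value ($14.50) and the printed aggregate benefit total
(≈$628k); those are the defaults, and `annualization_weeks` is
configurable. This is a reconstruction, not a documented convention.

**Timing and discounting.** All flows occur at end of year; year 1 is
undiscounted and year t is divided by 1.03^(t−1). The horizon is always
derived, never set: `n_cost_years + effect_length − 1` (6 years in the base
case), so the last cohort's benefits are fully counted when the effect
length changes. With these conventions the model reproduces the published
per-year discounted series (benefits ≈ 49/118/137/133/129/63 k$; year-5
cost ≈ $95k) and headline totals (costs ≈ $556k, benefits ≈ $631k,
BCR 1.13) to within the published rounding (≲1%).

## Sensitivity analysis

**One-way (tornado).** Each input moves to its published low and high
bound with everything else at base, and the full model is re-run. The
composites (abstinence difference 0.21–0.41, adherence gain 0.1475–0.2475)
are overridden directly since their ranges are stated on the composites.
Three program-level knobs are varied as well: effect length 1–10 years,
discount rate 0–6%, and participant transport reimbursement 0–500 KES per
visit — applied by rescaling the per-site ledger's participant-payments
line, never added on top of it. The rollout cost per participant (published
without bounds, "a broad range") defaults to 0.5×–2× the base $43.59,
applied by rescaling both ledgers.

**Probabilistic (Monte Carlo).** All tabulated inputs are drawn
simultaneously, 10,000 replications per effect-length scenario
(1, 2, 3, 4, 5, 10 years), and the deterministic model is re-run per
replicate. Distribution families follow the published hints:

* *Costs* (the four non-drug treatment components and the ARV drug cost)
  are log-normal, fitted so the published range is the central 95%
  interval: median = √(low·high), σ = ln(high/low)/(2·1.96). This
  range-fitted form is the default because the ARV cost's base value sits
  at its range's lower bound, where a median-at-base log-normal would put
  half its mass below the published sampling range; a `median_base` mode
  is available for comparison.
* *CI-backed inputs* are normal(base, SE): the labor-hours rise
  (SE 1.88 h on a 24.3 h baseline, i.e. 0.0774 on the fraction scale), the
  two household-hour gains (SE 0.461 and 0.556), and the
  alcohol-attributable fraction, whose asymmetric simulation range
  1.8–16.5% is read as that model's 95% uncertainty interval
  (SE = width/3.92 = 0.0375).
* *Everything else* (the two composites and the two wages) is uniform over
  its range.

Draws are clamped — fractions to [0, 1], monetary amounts and hours to
≥ 0 — and clamp counts are recorded per input (at base settings ≲1% of
draws, almost all from the labor-hours normal). Replicates share a seeded
`numpy` generator; each effect-length scenario uses an independent spawned
substream, so results are bit-reproducible from the master seed. Per
scenario the package reports the replicate mean, the 2.5–97.5 percentile
interval of the replicate ratios, and the normal-theory 95% interval of
the mean (the published intervals' construction is not stated, so both are
emitted). The program cost side is held at base in the PSA — only the
tabulated inputs are drawn — so all replicate variation is benefit-side.

Because the cost draws are right-skewed, the expected drawn treatment cost
exceeds its base value and the Monte Carlo mean BCR sits ~10–13% above the
deterministic ratio, reproducing the published scenario means (0.65, 1.28,
1.90, 2.49, 3.07, 5.72) within ~3% at 10,000 replications.

## Synthetic cohorts (microsimulation oracle)

The cohort-level benefit formulas are expectations over an implicit
person-level process; `cbtroi.microsim` simulates that process directly so
the closed forms can be checked by brute-force accounting. Per participant:
sex ~ Bernoulli(0.5); abstinence gain ~ Bernoulli(Δ); given abstinence,
full-adherence gain ~ Bernoulli(a); weekly labor-hour gain ~
normal(0.19 × 24.3, 1.88); female household hours ~ normal(1.056, 0.461) +
normal(1.945, 0.556). Hour draws below zero are clamped (counted; ~0.8% of
draws, a ≲0.1% upward bias on the benefit total, well inside the Monte
Carlo tolerance used in tests). Valuation and discounting reuse the
closed-form modules' conventions, so oracle and formula compare like with
like. What the generator does *not* emulate: correlation between sex and
labor-force outcomes, individual transmission events, attrition, or any
heterogeneity beyond the stated distributions — agreement here validates
the package's internal arithmetic, not the model's fidelity to real
Kenyan cohorts.

## Numerical choices and degenerate inputs

* Internal arithmetic is full-precision throughout; rounding (nearest
  $1,000 for totals, 2 dp for ratios, nearest dollar/half-dollar for
  per-person values) happens only in reporting.
* Tornado entries sort by spread descending with ties broken
  alphabetically, so output order is deterministic.
* A line item whose stated total contradicts units × unit cost by more
  than 1 KES is rejected; zero-cost programs raise an explicit error when
  the ratio is requested; a CPI lookup for a year missing from the index
  (e.g. 2012, for which no value is published and none is needed) fails
  loudly at use or load time.
* A failed PSA replicate aborts the run; replicates are never dropped
  silently.

## Limitations

* Effectiveness rests on a small pilot trial; the effect length — the
  single most influential input — has little direct evidence, which is why
  the 1–10-year scenario sweep is first-class.
* Benefits are monetized only through the three published channels; no
  QALY/DALY valuation, secondary-infection dynamics, or healthcare-system
  congestion effects.
* The single fixed exchange rate and constant-2013-USD framing ignore
  real FX and wage drift over the rollout.
* The PSA distribution shapes for cost inputs are a documented
  reconstruction (see above); alternative parameterizations shift the
  Monte Carlo means by up to ~20% while leaving the deterministic results
  untouched.
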