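# Base-case model inputs and sensitivity specification.
# Monetary values are USD unless the name says KES; hours are per week.
economic_context:
  discount_rate: 0.03
  exchange_rate_kes_per_usd: 84.53
  reference_year: 2013
  cpi:
    2009: 100.0
    2010: 106.265
    2011: 121.17
    2013: 140.103

model:
  p_abst_cbt: 0.69            # 90-day abstinence, CBT arm
  p_abst_uc: 0.38             # 90-day abstinence, usual care
  alcohol_attrib_frac: 0.13   # share of new HIV infections attributable to alcohol
  nondrug_costs_2009: [32.0, 24.0, 0.4, 32.0]  # lab, visits, support, fixed (2009 USD)
  arv_drug_cost: 145.47       # 12-month tenofovir/3TC/EFV, 2013 USD
  adherence_counts:           # non-adherent (events, exposed)
    hazardous: [19, 69]
    nondrinker: [112, 1439]
  lfp_rise: 0.19              # rise in weekly hours worked, fraction of baseline
  lfp_baseline_hours: 24.3
  lfp_se_hours: 1.88
  monthly_min_wage: 76.93     # mean monthly minimum wage, USD
  hp_hours_firewood: 1.056    # female weekly hour gain, firewood
  hp_hours_water: 1.945       # female weekly hour gain, water
  house_wage: 0.85            # house-worker hourly wage, USD
  female_fraction: 0.5
  effect_length: 2            # years the treatment effect is maintained
  annualization_weeks: 48.0   # weeks/year valuing weekly household hours
  months_per_year: 12

schedule:
  n_sites: 12
  participants_per_site_by_year: [160, 240, 240, 240, 240]
  transport_kes_per_visit: 200
  visits_per_participant: 6

# One record per varied input: range is the published sensitivity interval;
# normal_ci se values are the standard errors behind those intervals
# (lfp_rise se = 1.88 h / 24.3 h baseline; alcohol_attributable_fraction se
# = range width / (2 * 1.96), reading the simulation range as a 95% CI).
sensitivity:
  - {name: abstinence_difference, base: 0.31, low: 0.21, high: 0.41, units: fraction, distribution: uniform_range}
  - {name: alcohol_attributable_fraction, base: 0.13, low: 0.018, high: 0.165, units: fraction, distribution: normal_ci, se: 0.0375}
  # base is 19/69 - 112/1439 at full precision; it prints as 19.75%
  - {name: adherence_gain, base: 0.1975304911824838, low: 0.1475, high: 0.2475, units: fraction, distribution: uniform_range}
  - {name: nondrug_lab, base: 32.0, low: 29.2, high: 36.2, units: usd_2009, distribution: right_skewed_cost}
  - {name: nondrug_visits, base: 24.0, low: 18.8, high: 29.2, units: usd_2009, distribution: right_skewed_cost}
  - {name: nondrug_support, base: 0.4, low: 0.10, high: 0.90, units: usd_2009, distribution: right_skewed_cost}
  - {name: nondrug_fixed, base: 32.0, low: 22.4, high: 46.6, units: usd_2009, distribution: right_skewed_cost}
  - {name: arv_drug_cost, base: 145.47, low: 145.47, high: 280.72, units: usd_2013, distribution: right_skewed_cost}
  - {name: monthly_min_wage, base: 76.93, low: 57.42, high: 103.60, units: usd_per_month, distribution: uniform_range}
  - {name: lfp_rise, base: 0.19, low: 0.037, high: 0.34, units: fraction, distribution: normal_ci, se: 0.0773663}
  - {name: hp_firewood_hours, base: 1.056, low: 0.15, high: 1.96, units: hours_per_week, distribution: normal_ci, se: 0.461}
  - {name: hp_water_hours, base: 1.945, low: 0.86, high: 3.03, units: hours_per_week, distribution: normal_ci, se: 0.556}
  - {name: house_worker_wage, base: 0.85, low: 0.58, high: 1.03, units: usd_per_hour, distribution: uniform_range}

# Program-level knobs varied one-way only (not part of the simultaneous
# Monte Carlo draws). Bounds for the effect length are the published
# scenario set; the others are package defaults over plausible spans.
oneway_extras:
  - {name: effect_length_years, base: 2, low: 1, high: 10, units: years, distribution: uniform_range}
  - {name: discount_rate, base: 0.03, low: 0.0, high: 0.06, units: fraction, distribution: uniform_range}
  - {name: transport_kes_per_visit, base: 200, low: 0, high: 500, units: kes_per_visit, distribution: uniform_range}
  - {name: cbt_cost_per_participant, base: 43.59, low: 21.8, high: 87.2, units: usd, distribution: uniform_range}
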