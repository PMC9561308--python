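# Base-case model configuration: lenvatinib + pembrolizumab (LP) versus
# single-agent chemotherapy (50/50 doxorubicin/paclitaxel) for previously
# treated pMMR advanced endometrial cancer, Chinese payer perspective.
# Prices in USD.  Parameters with {base, low, high, dist} entries carry
# their one-way sensitivity range and probabilistic distribution family.

econ:
  cycle_length_days: 21.0
  horizon_years: 10.0
  wtp_per_qaly: 37663.26
  month_days: 30.4375
  half_cycle_correction: false
  occupancy: partitioned
  annual_discount_rate: {base: 0.05, low: 0.0, high: 0.08, dist: beta}
  bsa_m2: {base: 1.64, low: 1.288, high: 1.96, dist: beta}

# per-mg acquisition prices; pembrolizumab's one-way low is 50% of base
drug_prices:
  lenvatinib: {base: 4.255, low: 2.7575, high: 4.255, dist: gamma}
  pembrolizumab: {base: 25.98, low: 12.99, high: 25.98, dist: gamma}
  doxorubicin: {base: 0.3220, low: 0.1958, high: 0.4482, dist: gamma}
  paclitaxel: {base: 0.1138, low: 0.0692, high: 0.1584, dist: gamma}

# grade >=3 serious adverse events: management cost per cycle and
# utility decrement; incidences are per-arm below
ae_costs:
  hypertension: {base: 12.9, low: 11.6, high: 14.2, dist: gamma}
  anemia: {base: 73.68, low: 55.27, high: 92.11, dist: gamma}
  neutropenia: {base: 461.5, low: 415.4, high: 507.7, dist: gamma}
ae_disutilities:
  hypertension: {base: 0.1, low: 0.1, high: 0.15, dist: beta}
  anemia: {base: 0.074, low: 0.037, high: 0.11, dist: beta}
  neutropenia: {base: 0.2, low: 0.15, high: 0.25, dist: beta}

other_costs:
  bsc_per_cycle: {base: 55.6, low: 27.8, high: 83.4, dist: gamma}
  followup_per_cycle: {base: 337.50, low: 168.75, high: 506.25, dist: gamma}

utilities:
  pfd: {base: 0.817, low: 0.797, high: 0.836, dist: beta}
  pd: {base: 0.779, low: 0.699, high: 0.859, dist: beta}

# log-logistic S(t) = 1/(1 + scale * t**shape), t in months
survival:
  lp:
    pfs: {family: log-logistic, shape: 1.6294, scale: 0.04528}
    os: {family: log-logistic, shape: 1.5396, scale: 0.01375}
  chemo:
    pfs: {family: log-logistic, shape: 1.941, scale: 0.06522}
    os: {family: log-logistic, shape: 1.8582, scale: 0.01024}

strategies:
  lp:
    label: Lenvatinib plus Pembrolizumab
    treatment_duration_cycles: 11   # ceil(231-day median duration / 21)
    components:
      lenvatinib: {dose_rule: per_day_fixed_mg, dose: 20.0, weight: 1.0}
      pembrolizumab: {dose_rule: per_cycle_fixed_mg, dose: 200.0, weight: 1.0}
    ae_incidence:
      hypertension: 0.379
      anemia: 0.062
      neutropenia: 0.017
  chemo:
    label: Chemotherapy
    treatment_duration_cycles: 5    # ceil(104.5-day median duration / 21)
    components:
      # weekly 3-on/1-off paclitaxel mapped to the 21-day cycle: 3 doses
      # per 28 days -> 2.25 administrations per model cycle
      doxorubicin:
        {dose_rule: per_admin_bsa_mg_per_m2, dose: 60.0,
         administrations_per_cycle: 1.0, weight: 0.5}
      paclitaxel:
        {dose_rule: per_admin_bsa_mg_per_m2, dose: 80.0,
         administrations_per_cycle: 2.25, weight: 0.5}
    ae_incidence:
      hypertension: 0.023
      anemia: 0.147
      neutropenia: 0.258

metadata:
  currency: USD
  fx_note: prices converted at 6.45 CNY per USD (2021 average); no runtime conversion
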