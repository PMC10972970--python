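# Default model inputs: Evolut Low Risk trial event rates and French 2019 cost
# inputs for the TAVI-vs-SAVR cost-effectiveness model.
#
# Probabilities are cumulative incidences at 30 days / 12 months / 24 months,
# stored as decimals exactly as published. Costs are 2019 euros.

cohort:
  start_age: 73.9          # mean age at index treatment, years
  pct_female: 0.353
  n_tavi: 725              # as-treated arm sizes (used for PSA effective sample sizes)
  n_savr: 678

events:   # cumulative probability at [30 days, 12 months, 24 months]
  death:                 {TAVI: [0.004, 0.021, 0.035], SAVR: [0.012, 0.027, 0.044]}
  stroke:                {TAVI: [0.034, 0.043, 0.062], SAVR: [0.032, 0.043, 0.060]}
  mi:                    {TAVI: [0.008, 0.018, 0.021], SAVR: [0.013, 0.016, 0.016]}
  ppi:                   {TAVI: [0.171, 0.190, 0.218], SAVR: [0.060, 0.068, 0.077]}
  bleeding:              {TAVI: [0.066, 0.081, 0.104], SAVR: [0.104, 0.122, 0.137]}
  cardiogenic_shock:     {TAVI: [0.0, 0.0, 0.0],       SAVR: [0.0, 0.0, 0.0]}
  aki:                   {TAVI: [0.021, 0.021, 0.021], SAVR: [0.101, 0.101, 0.101]}
  major_vascular:        {TAVI: [0.037, 0.037, 0.039], SAVR: [0.031, 0.034, 0.036]}
  af:                    {TAVI: [0.075, 0.094, 0.122], SAVR: [0.355, 0.387, 0.397]}
  av_rehospitalization:  {TAVI: [0.012, 0.033, 0.049], SAVR: [0.024, 0.059, 0.072]}
  reintervention:        {TAVI: [0.003, 0.006, 0.009], SAVR: [0.003, 0.004, 0.009]}

costs:
  preoperative:      {TAVI: 3141, SAVR: 3112}
  index_procedure:   {TAVI: 23743, SAVR: 23324}   # incl. device and materials
  rehabilitation:    {TAVI: 74, SAVR: 652}        # based on utilization
  tavi_device_cost: 15419   # informational: already included in index_procedure
  acute_events:     # per-event acute treatment cost, events beyond first 30 days
    stroke: 5857
    mi: 5776
    ppi: 6734
    bleeding: 11282
    cardiogenic_shock: 4789
    aki: 4589
    major_vascular: 7511
    af: 3608
    av_rehospitalization: 4789
    reintervention: 23324
  followon:
    stroke_annual: 8530
    ppi_year1: 545
    ppi_year2plus: 273
  outpatient:       # per-patient follow-up cost schedule, identical across arms
    month_1: 237
    month_6: 60
    month_12: 18
    annual_beyond_12m: 262
  end_of_life: 0            # per-death one-off; published value unavailable
  transport_per_event: 0    # per acute event occurrence; published value unavailable
  ppi_postdischarge_fraction: 0.0   # share of 30-day pacemakers implanted after
                                    # discharge (only these incur acute cost in
                                    # cycle 1); published split unavailable

utilities:   # EQ-5D-5L (French value set) at months 1, 6, 12, and 13+
  no_stroke:
    TAVI: [0.847, 0.848, 0.825, 0.832]
    SAVR: [0.768, 0.826, 0.839, 0.832]
  post_stroke: [0.805, 0.789, 0.792, 0.792]   # pooled across arms

settings:
  horizon_months: 444          # lifetime: cohort reaches the age cap (110 y)
  discount_rate_annual: 0.025
  wtp_per_qaly: 50000
  rr_longterm: {TAVI: 1.0, SAVR: 1.0}   # multiplier on lifetable mortality beyond 24 m
  all_ae_continue: false       # scenario flag: continue all AEs beyond 24 m
  maintain_differential_utility: false
  longterm_rates: pooled       # 'pooled' (arm-averaged year-2 rates) or 'per_arm'
  gompertz_shape: 0.10         # per year, fixed slope of the synthetic lifetable
  le_target_male: 13.0         # complete life expectancy at age 74, years
  le_target_female: 15.8
  seed: 12345
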