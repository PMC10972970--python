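# Scenario registry: the named scenario analyses run alongside the base case.
# Each entry holds overrides applied on top of the default inputs; keys must
# exist in the model configuration (or be one of the special keys handled by
# sensitivity.apply_overrides: 'utilities_file').

base_undiscounted:
  description: Base case with discounting disabled
  overrides:
    discount_rate_annual: 0.0

horizon_15y:
  description: 15-year analysis horizon
  overrides:
    horizon_months: 180

horizon_2y:
  description: 2-year analysis horizon (current trial follow-up)
  overrides:
    horizon_months: 24

all_ae_continue:
  description: Consider all AEs in year 3 and following based on year 2 rates
  overrides:
    all_ae_continue: true

utilities_3l:
  description: Utilities scored with the EQ-5D-3L tariff (values not published;
    supply a utilities file to run)
  overrides:
    utilities_file: utilities_eq5d3l_placeholder.yaml

differential_utility_5l:
  description: Differential 12-month utility for SAVR and TAVI maintained over
    lifetime (EQ-5D-5L)
  overrides:
    maintain_differential_utility: true

differential_utility_3l:
  description: Differential utility maintained over lifetime (EQ-5D-3L; values
    not published; supply a utilities file to run)
  overrides:
    utilities_file: utilities_eq5d3l_placeholder.yaml
    maintain_differential_utility: true

rr_12_24:
  description: Lower long-term mortality based on 12-24-month trial data
    maintained over lifetime
  overrides:
    rr_longterm: {TAVI: 0.627, SAVR: 0.762}

rr_6_24:
  description: Lower long-term mortality based on 6-24-month trial data
    maintained over lifetime
  overrides:
    rr_longterm: {TAVI: 0.711, SAVR: 0.773}

rr_tavi_1_03:
  description: Higher long-term mortality for TAVI (RR 1.03 vs lifetables)
  overrides:
    rr_longterm: {TAVI: 1.03, SAVR: 1.0}

rr_tavi_1_05:
  description: Higher long-term mortality for TAVI (RR 1.05 vs lifetables)
  overrides:
    rr_longterm: {TAVI: 1.05, SAVR: 1.0}

rr_both_1_2:
  description: Higher relative mortality of both strategies (RR 1.2 vs lifetables)
  overrides:
    rr_longterm: {TAVI: 1.2, SAVR: 1.2}

rr_both_0_751:
  description: Lower relative mortality of both strategies (RR 0.751 vs lifetables)
  overrides:
    rr_longterm: {TAVI: 0.751, SAVR: 0.751}
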