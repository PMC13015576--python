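# Scenario 3: toxicity occurred on first-line capecitabine monotherapy.
# Three strategies; both continuation arms are oral first-line treatments.
scenario:
  name: cap_mono
  reference: stop_irinotecan
  strategies:
    - name: stop_irinotecan
      first_line_class: none
      first_line: null
      second_line:
        name: irinotecan_mono
        cycle_weeks: 3
        drug_components: {irinotecan_mono: 677}
        admin_components: {admin_short: 335}
      rr_os: 1.50
      rr_ttp: 1.50
      ae: {p_hfs: 0.0, p_cvt: 0.0}
    - name: reduced_cap_capox
      first_line_class: fluoropyrimidine
      first_line:
        name: reduced_capecitabine
        cycle_weeks: 3
        drug_components: {capecitabine_reduced: 180}
        admin_components: {}
      second_line:
        name: capox
        cycle_weeks: 3
        drug_components: {capecitabine_reduced: 180, oxaliplatin: 556}
        admin_components: {admin_short: 335}
      rr_os: 1.0
      rr_ttp: 1.0
      ae: {p_hfs: 0.55, p_cvt: 0.40}
    - name: s1_sox
      first_line_class: s1
      first_line:
        name: s1_mono
        cycle_weeks: 3
        drug_components: {s1_mono: 398}
        admin_components: {}
      second_line:
        name: sox
        cycle_weeks: 3
        drug_components: {s1_combo: 331, oxaliplatin: 556}
        admin_components: {admin_short: 335}
      rr_os: 0.93
      rr_ttp: 1.0
      ae: {p_hfs: 0.05, p_cvt: 0.04}

settings:
  horizon_weeks: 780
  weeks_per_year: 52.18
  discount_costs: 0.03
  discount_qalys: 0.015
  p_second_line: 0.80
  cohort_size: 1000

utilities:
  first_line: 0.83
  decrement_second_line: 0.15
  decrement_progressed_untreated: 0.10

survival:
  os: {shape: 1.473, scale: 79.4}
  ttp: {shape: 1.560, scale: 53.9}

psa:
  rr_s1: {mu: -0.0726, sigma: 0.058}
  utility: {mean: 0.83, sd: 0.01}
  os: {sd_shape: 0.096, sd_scale: 4.874, corr: 0.555}
  ttp: {sd_shape: 0.107, sd_scale: 3.243, corr: -0.255}
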