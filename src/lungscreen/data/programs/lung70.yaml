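# Universal age-based (40-85) LDCT lung screening at observed 14.4% uptake.
# Calibration cells are the published program operating points; CIs are 95%.
name: lung70
eligible_population: 155500000.0
participation: 0.70
stage1_detection: 0.30
all_cause_reduction: 0.067
qaly_weight_mean: 0.85
qaly_weight_sd: 0.05
discount_rate: 0.03
icer_from_formula: true
gross_treatment_savings_70: 24760000000.0
neutrality_anchor: 0.76
calibration:
  - participation: 0.144
    annual_screen_volume: 13200000.0
    annual_cost: {mean: 2100000000.0, lo: 1500000000.0, hi: 2800000000.0}
    lives_cancer: {mean: 20500.0, lo: 12000.0, hi: 29000.0}
    lives_all_cause: {mean: 103000.0, lo: 70000.0, hi: 140000.0}
  - participation: 0.70
    annual_screen_volume: 64100000.0
    annual_cost: {mean: 12800000000.0, lo: 8800000000.0, hi: 16800000000.0}
    lives_cancer: {mean: 99700.0, lo: 55300.0, hi: 144100.0}
    lives_all_cause: {mean: 500600.0, lo: 339900.0, hi: 661300.0}
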