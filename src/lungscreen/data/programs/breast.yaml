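# Biennial mammography ages 40-74 at 67% participation (benchmark comparator:
# published outputs are inputs here, not re-derived). The cost, lives and
# ICER cells are the published benchmark values; eligible_population and
# annual_screen_volume are synthetic plausible magnitudes used only for
# display.
name: breast
eligible_population: 44000000.0
participation: 0.67
icer_from_formula: false
qaly_weight_mean: 0.85
qaly_weight_sd: 0.05
discount_rate: 0.03
calibration:
  - participation: 0.67
    annual_screen_volume: 29500000.0
    annual_cost: {mean: 9500000000.0, lo: 7000000000.0, hi: 12000000000.0}
    lives_cancer: {mean: 10700.0, lo: 8700.0, hi: 12700.0}
    icer_input: {mean: 50000.0, lo: 40000.0, hi: 60000.0}
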