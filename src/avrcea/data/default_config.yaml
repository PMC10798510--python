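# Default model configuration: 65-year-old Thai cohort, 3%/3% discounting,
# societal perspective, WTP 160,000 THB/QALY, 2022 PPP 11.72 THB/USD.
start_age: 65
cycle_length: 1.0
max_age: 100
discount_cost: 0.03
discount_health: 0.03
perspective: societal
stratum: overall
wtp: 160000.0
ppp: 11.72
psa_iterations: 1000
seed: 20220
half_cycle: false
accrual: start
long_term_mortality: combined
utility_timing: u30d_first_cycle
se_rule: range_as_95ci
parameters_csv: parameters.csv
life_table_csv: thai_life_table_synthetic.csv
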