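# Balanced 4-group design: 500 respondents per group, 20 items, the first
# 4 items carry DIF (slope offsets +-0.5, intercept offsets +-1.0 with
# alternating signs across groups 2-4), impact means within [-0.5, 0.5].
S: 4
group_sizes: [500, 500, 500, 500]
J: 20
n_dif_items: 4
dif_a: 0.5
dif_b: 1.0
impact_means: [0.0, -0.5, 0.0, 0.5]
impact_var: 1.0
missing_rate: 0.0
seed: 1
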