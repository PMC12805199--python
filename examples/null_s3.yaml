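# Null design: 3 groups with impact (means 0 / -0.3 / 0.3) but no DIF on
# any item; used to check false-positive calibration.
S: 3
group_sizes: [500, 500, 500]
J: 15
n_dif_items: 0
dif_a: 0.0
dif_b: 0.0
impact_means: [0.0, -0.3, 0.3]
impact_var: 1.0
missing_rate: 0.0
seed: 1
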