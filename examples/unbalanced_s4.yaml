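# Unbalanced 4-group design with geometrically decaying group shares
# (each group half the size of the previous), same DIF structure as the
# balanced scenario.
S: 4
group_sizes: [1067, 533, 267, 133]
J: 20
n_dif_items: 4
dif_a: 0.5
dif_b: 1.0
impact_means: [0.0, -0.5, 0.0, 0.5]
impact_var: 1.0
missing_rate: 0.0
seed: 1
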