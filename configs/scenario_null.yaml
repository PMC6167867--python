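# One null-hypothesis cohort: equal IE probability and equal hazards in
# both arms, hazard halved after the IE, no administrative censoring.
theta_A: 0.5
theta_B: 0.5
lambda0_A: 1.0
lambda0_B: 1.0
m1_A: 2.0
m1_B: 2.0
c_p: 0.0
n_per_group: 200
seed: 1
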