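# Power grid: post-IE mean survival differs between arms (m1_B varies),
# IE probability balanced so every test holds its size.
defaults:
  theta_A: 0.5
  theta_B: 0.5
  lambda0_A: 1.0
  lambda0_B: 1.0
  m1_A: 2.0
  c_p: 0.0
  n_reps: 1000
scenarios:
  - {m1_B: 1.5, n_per_group: 50}
  - {m1_B: 1.25, n_per_group: 50}
  - {m1_B: 1.0, n_per_group: 50}
  - {m1_B: 1.5, n_per_group: 100}
  - {m1_B: 1.25, n_per_group: 100}
  - {m1_B: 1.0, n_per_group: 100}
  - {m1_B: 1.5, n_per_group: 200}
  - {m1_B: 1.25, n_per_group: 200}
  - {m1_B: 1.0, n_per_group: 200}
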