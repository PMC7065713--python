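# Flat single-level comparator on the grating space: "absent" is an
# ordinary stimulus class under a uniform three-class prior.
n_states: 2
feature_dim: 2
means:
  - [3.5, 3.5]
  - [7.0, 3.5]
  - [3.5, 7.0]
covariance:
  - [1.0, 0.0]
  - [0.0, 1.0]
flat_prior: [0.33333333333333331, 0.33333333333333331, 0.33333333333333337]
state_labels: [absent, grating_1, grating_2]
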