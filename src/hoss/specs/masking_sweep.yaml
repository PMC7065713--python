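# Masking-experiment parameter set: the grating discrimination space
# plus the default precision multipliers standing in for increasing
# stimulus-onset asynchrony (covariance becomes Sigma / lambda for both
# generation and inference).
n_states: 2
feature_dim: 2
means:
  - [3.5, 3.5]   # absent (w0)
  - [7.0, 3.5]   # grating_1
  - [3.5, 7.0]   # grating_2
covariance:
  - [1.0, 0.0]
  - [0.0, 1.0]
prior_presence: 0.5
prior_content_given_presence: [0.5, 0.5]
state_labels: [absent, grating_1, grating_2]
precision_grid: [0.02, 0.05, 0.1, 0.2, 0.5, 1.0, 2.0]
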