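# Near-threshold detection/discrimination space: two content classes
# one noise-SD away from the absent class. Used for the posterior,
# confidence and belief-update lattice maps.
n_states: 2
feature_dim: 2
means:
  - [0.5, 0.5]   # absent (w0)
  - [1.5, 0.5]   # w1 (feature axis 1)
  - [0.5, 1.5]   # w2 (feature axis 2)
covariance:
  - [1.0, 0.0]
  - [0.0, 1.0]
prior_presence: 0.5
prior_content_given_presence: [0.5, 0.5]
state_labels: [absent, w1, w2]
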