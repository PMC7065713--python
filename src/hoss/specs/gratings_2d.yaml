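# Two-class "grating tilt" discrimination space with well-separated
# classes: each feature axis carries the activation of one tilt, the
# absent class sits at low activation on both. Unit noise covariance.
n_states: 2
feature_dim: 2
means:
  - [3.5, 3.5]   # absent (w0)
  - [7.0, 3.5]   # grating_1 (feature axis 1)
  - [3.5, 7.0]   # grating_2 (feature axis 2)
covariance:
  - [1.0, 0.0]
  - [0.0, 1.0]
prior_presence: 0.5
prior_content_given_presence: [0.5, 0.5]
state_labels: [absent, grating_1, grating_2]
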