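# Methods

## Generative model

The observer's world has two latent levels. An awareness state
A ∈ {a₀, a₁} with prior P(a₁) generates a content state
W ∈ {w₀, w₁, …, w_N}: absence forces the no-content state
(P(w₀|a₀) = 1) and presence distributes its mass over the N content
states with the conditional prior P(wᵢ|a₁), leaving w₀ no mass under
a₁. The content state then emits a feature vector X ~ N(μ_W, Σ) in an
M-dimensional feature space; Σ is shared by all N+1 states and known to
the observer. The mean matrix therefore has N+1 columns — the no-content
state is a proper emission class (low feature activation), not a missing
observation.

Because the hierarchy is a chain A → W → X with discrete upper levels,
exact inference is a finite sum. The implementation collapses the two
levels into the induced marginal prior over (w₀ … w_N),

    π = (1 − P(a₁), P(a₁)P(w₁|a₁), …, P(a₁)P(w_N|a₁)),

applies Bayes' rule once, and reads P(a₁|x) off as the posterior mass on
the content entries. A reference oracle (`posterior_oracle`) instead
enumerates the full 2×(N+1) joint table including the zero-mass pairs
and normalizes it wholesale; a property test holds the two routes to
1e-10 agreement over randomized models. This dual-route check is the
correctness argument for the inference engine.

## Readouts

- **Report**: "seen" iff P(a₁|x) strictly exceeds the threshold
  (default 0.5). A posterior exactly at threshold reads out "unseen" —
  the strict inequality resolves the tie deterministically.
- **Confidence in identity**: max over the *marginal* content
  posteriors P(w₁|x) … P(w_N|x). This is deliberately not renormalized
  by P(a₁|x): confidence and visibility then dissociate, which is the
  phenomenon of interest. (Conditioning on presence would be the other
  defensible reading; it is not provided.)
- **Belief update** (Bayesian surprise), in nats: KL(posterior ‖ prior)
  at each level — the categorical divergence over (w₀ … w_N) against π
  at the W level, the Bernoulli divergence of P(a₁|x) against P(a₁) at
  the A level. Direction is fixed as posterior-from-prior, the standard
  surprise convention; the posterior's support is always contained in
  the prior's (posterior ∝ prior × likelihood), so the divergence is
  finite by construction and the code asserts it. An alternative W-level
  mode sums per-node binary-marginal divergences ("per_node_sum"),
  reading each w_k as an on/off node of a network layer; it
  double-counts shared mass movements and so lives on a different scale
  from the joint mode — the two are never mixed in one analysis.

## Priors

"Flat priors at both levels" is implemented as *conditionally* flat:
P(a₁) = 0.5 and P(wᵢ|a₁) = 1/N. The induced marginal
(0.5, 0.5/N, …) is then not uniform over the N+1 states; a uniform
marginal would contradict a flat awareness prior whenever N > 1, so the
hierarchical reading is the only self-consistent one. The packaged
parameter sets use these priors; both are configurable.

## Flat comparator

The single-level comparator keeps the identical Gaussian emissions and
classifies over all N+1 classes under one prior (uniform by default).
With the hierarchical priors chosen to induce the same marginal, the two
architectures produce *identical* state posteriors — they differ only in
prior structure and in having a presence query — which isolates the
architectural contribution to any behavioural difference. The flat
model has no awareness variable, so a report rule is imposed: seen iff
P(absent|x) < 0.5 (mirroring the hierarchical threshold on
1 − P(absent)); an argmax rule is available as an option.

## Simulation experiments

**Lattice maps** evaluate the readouts on a regular 2D grid. The CLI
default is [−1, 3]² at step 0.1, sized for the near-threshold set;
[0, 10]² covers the grating set. Extents are chosen to cover the class
means with a margin of about two noise SDs, with a step fine enough to
resolve the 0.5 decision contour. Lattice points on the contour are flagged:
a point is "on contour" if P(a₁|x) − ½ is exactly zero or changes sign
against a 4-neighbour, the discrete trace of the decision boundary.

**Trial sampler.** Trials are drawn from the model's own generative
process: equal counts per class (configurable via a class subset), each
class from its Gaussian at the current precision. Randomness uses one
`SeedSequence` root per run with one spawned child stream per class, so
adding or dropping classes never perturbs the draws of the remaining
classes, and runs are bit-for-bit reproducible for a given seed.

**Masking sweep.** Stimulus-onset asynchrony is modelled as a scalar
precision multiplier λ: both the generative and the observer covariance
become Σ/λ (the observer is matched to the world; precision *inference*
is out of scope). The default grid λ ∈ {0.02, 0.05, 0.1, 0.2, 0.5, 1, 2}
spans seen-rates for present-class trials from near chance to near
ceiling on the grating set; λ = 100 serves as the effectively noiseless
endpoint. Default 2000 trials per class per level — small enough to run
in well under a second, large enough that binomial error on a seen-rate
is ≈ 0.011. Per-level summaries condition purely on the model's own
report (misclassified absent-class trials pool into "seen"); an empty
report category yields an explicitly missing (NaN) mean with a zero
count, never a silent zero.

## What the simulations do and do not emulate

The sampler realizes exactly the model's assumptions: Gaussian,
isotropic-by-default noise; a single shared covariance; i.i.d. trials;
an observer that knows all generative parameters including the noise
level. Passing tests therefore demonstrate internal consistency of the
architecture and the claimed qualitative patterns — graded detection
posteriors, confidence/visibility dissociation, asymmetric W-level vs
symmetric A-level surprise, ignition growth with precision — not fits
to empirical masking data. Real psychophysics adds criterion drift,
non-Gaussian and correlated noise, precision misestimation and serial
dependencies, none of which are modelled.

## Numerical choices

- All probability arithmetic is done in log space with log-sum-exp
  normalization; likelihood evaluation goes through a cached Cholesky
  factor of Σ (one triangular solve covers all samples and classes).
  Posteriors remain normalized to 1e-12 even ~100 SDs from every mean,
  where raw densities underflow to zero.
- KL values are clamped at zero: Gibbs' inequality guarantees
  nonnegativity, and the clamp removes float round-off of order 1e-16
  at posterior≈prior points.
- Covariance validity is decided by Cholesky success; symmetry is
  checked to 1e-12 first so the error message can distinguish the two
  failure modes.
- Degenerate priors (P(a₁) ∈ {0, 1}) are supported: log 0 = −inf is
  harmless under log-sum-exp and the affected states simply carry zero
  posterior mass.
- CSV output is deterministic (fixed column order, pandas' shortest
  round-trip float formatting, `\n` line endings); every CLI output is
  paired with a JSON manifest carrying the resolved config, seed,
  package version and SHA-256 hashes, so any file is reproducible from
  its manifest alone.

## Known limitations

- Exact enumeration scales linearly in N+1 but the state space is flat;
  deeply structured content hierarchies would need a different
  inference scheme.
- Σ is shared across states by design; per-class covariance is not
  supported.
- No learning of priors or state spaces, no reaction times, no neural
  dynamics or message passing — the model is a computational-level
  account of the report, not of its time course.
- The feature-axis convention is fixed (axis i carries evidence for
  content state wᵢ); display labels are metadata and never enter the
  math.
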