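"""Higher-order state space (HOSS) generative model and exact inference.

The model places a binary awareness state ``A`` (absent ``a0`` / present
``a1``) above a discrete perceptual-content state ``W`` taking values
``w0 … wN``, where ``w0`` is the no-content state. The nesting is
asymmetric: presence entails content (``P(w0 | a1) = 0``) and absence
entails no content (``P(w0 | a0) = 1``). Each state ``wk`` emits a sensory
feature vector ``x`` from a multivariate Gaussian with mean ``mu[:, k]``
and a covariance ``Sigma`` shared across states.

Reports of "seen"/"unseen" are read out from the posterior over ``A``,
obtained by marginalizing the content states; confidence in identity is
the largest content-state marginal. Belief updates (Bayesian surprise)
are KL divergences from prior to posterior at each level, in nats.

All probability arithmetic runs in log space with log-sum-exp
normalization, so posteriors stay normalized even for samples far from
every class mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import cholesky, solve_triangular
from scipy.special import logsumexp

__all__ = [
    "ModelSpec",
    "PosteriorBundle",
    "BeliefUpdate",
    "SpecValidationError",
    "class_likelihoods",
    "log_class_likelihoods",
    "posterior_presence",
    "posterior_states",
    "infer",
    "infer_batch",
    "belief_update",
    "posterior_oracle",
    "categorical_kl",
    "bernoulli_kl",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


class SpecValidationError(ValueError):
    """A model specification violates one of its invariants.

    The message always names the offending field.
    """


def _as_float_array(value, name: str, ndim: int) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim != ndim:
        raise SpecValidationError(f"{name}: expected a {ndim}-dimensional array, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise SpecValidationError(f"{name}: contains non-finite entries")
    return arr


@dataclass(frozen=True)
class ModelSpec:
    """Full specification of the two-level generative model.

    Parameters
    ----------
    means
        ``(M, N+1)`` matrix of emission means in feature-activation
        units. Column 0 is the absent state ``w0``; columns ``1 … N`` are
        the content states.
    covariance
        ``(M, M)`` symmetric positive-definite covariance shared by all
        states.
    prior_presence
        ``P(A = a1)`` in ``[0, 1]``.
    prior_content_given_presence
        Length-``N`` vector ``P(wi | a1)`` summing to 1.
    state_labels
        Optional ``N+1`` display names, defaulting to
        ``("absent", "w1", …)``. Labels are metadata only; feature axis
        ``i`` carries the evidence for content state ``wi`` regardless of
        how it is labelled.
    """

    means: np.ndarray
    covariance: np.ndarray
    prior_presence: float
    prior_content_given_presence: np.ndarray
    state_labels: tuple[str, ...] = ()
    _chol_lower: np.ndarray = field(init=False, repr=False, compare=False)
    _log_det_cov: float = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        means = _as_float_array(self.means, "means", 2)
        cov = _as_float_array(self.covariance, "covariance", 2)
        pw = _as_float_array(self.prior_content_given_presence, "prior_content_given_presence", 1)

        m, n_cols = means.shape
        if n_cols < 2:
            raise SpecValidationError("means: needs at least 2 columns (absent state plus one content state)")
        n = n_cols - 1
        if cov.shape != (m, m):
            raise SpecValidationError(
                f"covariance: expected shape ({m}, {m}) to match means rows, got {cov.shape}"
            )
        if not np.allclose(cov, cov.T, atol=1e-12):
            raise SpecValidationError("covariance: not symmetric")
        try:
            lower = cholesky(cov, lower=True)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - scipy raises LinAlgError
            raise SpecValidationError("covariance: not positive-definite (Cholesky failed)") from exc
        except Exception as exc:
            raise SpecValidationError("covariance: not positive-definite (Cholesky failed)") from exc

        pa = float(self.prior_presence)
        if not np.isfinite(pa) or not 0.0 <= pa <= 1.0:
            raise SpecValidationError(f"prior_presence: must lie in [0, 1], got {self.prior_presence}")
        if pw.shape != (n,):
            raise SpecValidationError(
                f"prior_content_given_presence: expected length {n} (one entry per content state), got {pw.shape}"
            )
        if np.any(pw < 0):
            raise SpecValidationError("prior_content_given_presence: entries must be nonnegative")
        if abs(pw.sum() - 1.0) > 1e-12:
            raise SpecValidationError(
                f"prior_content_given_presence: must sum to 1 within 1e-12, got {pw.sum()!r}"
            )

        labels = tuple(self.state_labels) if self.state_labels else ()
        if not labels:
            labels = ("absent",) + tuple(f"w{i}" for i in range(1, n + 1))
        if len(labels) != n + 1:
            raise SpecValidationError(f"state_labels: expected {n + 1} labels, got {len(labels)}")

        means = np.ascontiguousarray(means)
        means.setflags(write=False)
        cov = np.ascontiguousarray(cov)
        cov.setflags(write=False)
        pw = np.ascontiguousarray(pw)
        pw.setflags(write=False)

        object.__setattr__(self, "means", means)
        object.__setattr__(self, "covariance", cov)
        object.__setattr__(self, "prior_presence", pa)
        object.__setattr__(self, "prior_content_given_presence", pw)
        object.__setattr__(self, "state_labels", labels)
        object.__setattr__(self, "_chol_lower", lower)
        object.__setattr__(self, "_log_det_cov", 2.0 * float(np.sum(np.log(np.diag(lower)))))

    @property
    def n_states(self) -> int:
        """Number of content states N (absent state not counted)."""
        return self.means.shape[1] - 1

    @property
    def feature_dim(self) -> int:
        return self.means.shape[0]

    @property
    def marginal_prior(self) -> np.ndarray:
        """Induced marginal prior over ``(w0, w1, …, wN)``; sums to 1."""
        pa = self.prior_presence
        return np.concatenate(([1.0 - pa], pa * self.prior_content_given_presence))

    def with_precision(self, lam: float) -> "ModelSpec":
        """Scale sensory precision: replace Sigma with Sigma / lam.

        ``lam`` is the precision multiplier used in the masking sweep
        (larger lam = less sensory noise, i.e. longer SOA).
        """
        if not lam > 0:
            raise ValueError(f"precision multiplier must be positive, got {lam}")
        return ModelSpec(
            means=self.means,
            covariance=self.covariance / float(lam),
            prior_presence=self.prior_presence,
            prior_content_given_presence=self.prior_content_given_presence,
            state_labels=self.state_labels,
        )

    def validate_sample(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.shape != (self.feature_dim,):
            raise ValueError(
                f"sample dimension mismatch: expected shape ({self.feature_dim},), got {x.shape}"
            )
        if not np.all(np.isfinite(x)):
            raise ValueError("sample contains non-finite entries")
        return x


@dataclass(frozen=True)
class PosteriorBundle:
    """Posterior summary for a single sensory sample.

    ``p_states`` is the marginal posterior over ``(w0, …, wN)``;
    ``p_presence`` equals the sum of its content entries. ``confidence``
    is the largest content-state marginal (confidence in identity) and
    ``report`` is "seen" iff ``p_presence`` strictly exceeds the report
    threshold.
    """

    p_presence: float
    p_states: np.ndarray
    confidence: float
    report: str


@dataclass(frozen=True)
class BeliefUpdate:
    """Prior-to-posterior KL divergence at each level, in nats."""

    kl_w: float
    kl_a: float


def _log_likelihood_matrix(spec: ModelSpec, x_batch: np.ndarray) -> np.ndarray:
    """Gaussian log densities, shape ``(n_samples, N+1)``.

    Entry ``[i, k]`` is ``log N(x_i; mu_k, Sigma)``, evaluated via the
    cached Cholesky factor so that a single triangular solve covers all
    samples and states.
    """
    m = spec.feature_dim
    n_states = spec.means.shape[1]
    # deviations: (n, k, m) -> flatten to (n*k, m) for one triangular solve
    dev = x_batch[:, None, :] - spec.means.T[None, :, :]
    flat = dev.reshape(-1, m).T  # (m, n*k)
    z = solve_triangular(spec._chol_lower, flat, lower=True)
    quad = np.sum(z * z, axis=0).reshape(len(x_batch), n_states)
    return -0.5 * (m * _LOG_2PI + spec._log_det_cov + quad)


def log_class_likelihoods(spec: ModelSpec, x) -> np.ndarray:
    """Log density of ``x`` under each of the ``N+1`` class Gaussians."""
    x = spec.validate_sample(x)
    return _log_likelihood_matrix(spec, x[None, :])[0]


def class_likelihoods(spec: ModelSpec, x) -> np.ndarray:
    """Density of ``x`` under each class Gaussian (may underflow far out;
    prefer :func:`log_class_likelihoods` for arithmetic)."""
    return np.exp(log_class_likelihoods(spec, x))


def _posterior_states_batch(spec: ModelSpec, x_batch: np.ndarray) -> np.ndarray:
    """Marginal posterior over ``(w0 … wN)`` for each row of ``x_batch``."""
    log_lik = _log_likelihood_matrix(spec, x_batch)
    with np.errstate(divide="ignore"):
        log_prior = np.log(spec.marginal_prior)
    log_joint = log_prior[None, :] + log_lik
    log_post = log_joint - logsumexp(log_joint, axis=1, keepdims=True)
    return np.exp(log_post)


def posterior_states(spec: ModelSpec, x) -> np.ndarray:
    """Posterior over the expanded state space ``(w0, w1, …, wN)``.

    Bayes' rule with the induced marginal prior
    ``(1 - P(a1), P(a1) P(w1|a1), …)``; the result sums to 1.
    """
    x = spec.validate_sample(x)
    return _posterior_states_batch(spec, x[None, :])[0]


def posterior_presence(spec: ModelSpec, x) -> float:
    """Posterior probability of awareness, ``P(a1 | x)``.

    Marginalizes the content states: the presence posterior is the total
    posterior mass on ``w1 … wN``.
    """
    return float(posterior_states(spec, x)[1:].sum())


def infer(spec: ModelSpec, x, report_threshold: float = 0.5) -> PosteriorBundle:
    """Full inference for one sample: posteriors, confidence, report.

    ``report`` is "seen" iff ``P(a1|x)`` strictly exceeds
    ``report_threshold`` (a posterior exactly at threshold reads out as
    "unseen").
    """
    if not 0.0 < report_threshold < 1.0:
        raise ValueError(f"report_threshold must lie in (0, 1), got {report_threshold}")
    p_states = posterior_states(spec, x)
    p_presence = float(p_states[1:].sum())
    confidence = float(p_states[1:].max())
    report = "seen" if p_presence > report_threshold else "unseen"
    return PosteriorBundle(p_presence=p_presence, p_states=p_states, confidence=confidence, report=report)


def infer_batch(spec: ModelSpec, x_batch, report_threshold: float = 0.5):
    """Vectorized inference over a batch of samples.

    Returns ``(p_states, p_presence, confidence, seen)`` arrays with one
    row/entry per sample; used by the lattice maps and trial simulator.
    """
    if not 0.0 < report_threshold < 1.0:
        raise ValueError(f"report_threshold must lie in (0, 1), got {report_threshold}")
    x_batch = np.asarray(x_batch, dtype=float)
    if x_batch.ndim != 2 or x_batch.shape[1] != spec.feature_dim:
        raise ValueError(
            f"batch shape mismatch: expected (n, {spec.feature_dim}), got {x_batch.shape}"
        )
    p_states = _posterior_states_batch(spec, x_batch)
    p_presence = p_states[:, 1:].sum(axis=1)
    confidence = p_states[:, 1:].max(axis=1)
    seen = p_presence > report_threshold
    return p_states, p_presence, confidence, seen


def categorical_kl(p: np.ndarray, q: np.ndarray) -> float:
    """KL(p || q) in nats for categorical distributions, 0 log 0 := 0.

    Requires ``support(p) ⊆ support(q)``.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    mask = p > 0
    if np.any(q[mask] == 0):
        raise AssertionError("posterior has mass outside the prior support")
    # clamp float round-off: KL is nonnegative by Gibbs' inequality
    return max(0.0, float(np.sum(p[mask] * (np.log(p[mask]) - np.log(q[mask])))))


def bernoulli_kl(p: float, q: float) -> float:
    """KL between Bernoulli(p) and Bernoulli(q) in nats."""
    return categorical_kl(np.array([p, 1.0 - p]), np.array([q, 1.0 - q]))


def _kl_w_from_posterior(p_states: np.ndarray, prior: np.ndarray, mode: str) -> float:
    if mode == "joint":
        return categorical_kl(p_states, prior)
    if mode == "per_node_sum":
        # one binary (on/off) KL per W node, summed across nodes
        total = 0.0
        for pk, qk in zip(p_states, prior):
            total += categorical_kl(np.array([pk, 1.0 - pk]), np.array([qk, 1.0 - qk]))
        return total
    raise ValueError(f"unknown kl_w mode {mode!r}; use 'joint' or 'per_node_sum'")


def belief_update(spec: ModelSpec, x, kl_w_mode: str = "joint") -> BeliefUpdate:
    """Bayesian surprise at both levels for one sample, in nats.

    ``kl_w`` is the divergence of the posterior over ``(w0 … wN)`` from
    the induced marginal prior: either of the full categorical
    distribution (``"joint"``, the default) or the sum of per-node
    binary-marginal divergences (``"per_node_sum"``). ``kl_a`` is the
    Bernoulli divergence of ``P(a1|x)`` from the presence prior. Both are
    zero exactly when the posterior equals the prior.
    """
    p_states = posterior_states(spec, x)
    prior = spec.marginal_prior
    kl_w = _kl_w_from_posterior(p_states, prior, kl_w_mode)
    kl_a = bernoulli_kl(float(p_states[1:].sum()), spec.prior_presence)
    return BeliefUpdate(kl_w=kl_w, kl_a=kl_a)


def belief_update_batch(spec: ModelSpec, p_states: np.ndarray, kl_w_mode: str = "joint"):
    """Vectorized surprise from precomputed posteriors; returns (kl_w, kl_a)."""
    prior = spec.marginal_prior
    with np.errstate(divide="ignore", invalid="ignore"):
        log_prior = np.log(prior)
        if kl_w_mode == "joint":
            terms = np.where(p_states > 0, p_states * (np.log(np.where(p_states > 0, p_states, 1.0)) - log_prior[None, :]), 0.0)
            kl_w = terms.sum(axis=1)
        elif kl_w_mode == "per_node_sum":
            comp = 1.0 - p_states
            comp_prior = 1.0 - prior

            def _xlogx_over(p, q):
                return np.where(p > 0, p * (np.log(np.where(p > 0, p, 1.0)) - np.log(q)), 0.0)

            kl_w = (_xlogx_over(p_states, prior[None, :]) + _xlogx_over(comp, comp_prior[None, :])).sum(axis=1)
        else:
            raise ValueError(f"unknown kl_w mode {kl_w_mode!r}; use 'joint' or 'per_node_sum'")

        p = p_states[:, 1:].sum(axis=1)
        q = spec.prior_presence
        kl_a = np.where(p > 0, p * (np.log(np.where(p > 0, p, 1.0)) - np.log(q)), 0.0) + np.where(
            p < 1, (1 - p) * (np.log(np.where(p < 1, 1 - p, 1.0)) - np.log(1 - q)), 0.0
        )
    return np.maximum(kl_w, 0.0), np.maximum(kl_a, 0.0)


def posterior_oracle(spec: ModelSpec, x, report_threshold: float = 0.5) -> PosteriorBundle:
    """Reference inference via the fully expanded joint table over (A, W).

    Builds ``P(A) P(W|A) L(x|W)`` for every (A, W) pair — including the
    zero-prior-mass combinations the nesting rules out — normalizes the
    whole table, and reads both marginals off by summation. Serves as an
    independent cross-check for :func:`infer`, which instead uses the
    collapsed marginal prior.
    """
    if not 0.0 < report_threshold < 1.0:
        raise ValueError(f"report_threshold must lie in (0, 1), got {report_threshold}")
    x = spec.validate_sample(x)
    n = spec.n_states
    log_lik = log_class_likelihoods(spec, x)

    # P(W | A) table, rows a0/a1, cols w0..wN; absence forces w0,
    # presence distributes prior_content over w1..wN.
    p_w_given_a = np.zeros((2, n + 1))
    p_w_given_a[0, 0] = 1.0
    p_w_given_a[1, 1:] = spec.prior_content_given_presence
    p_a = np.array([1.0 - spec.prior_presence, spec.prior_presence])

    with np.errstate(divide="ignore"):
        log_joint = np.log(p_a)[:, None] + np.log(p_w_given_a) + log_lik[None, :]
    log_norm = logsumexp(log_joint)
    joint = np.exp(log_joint - log_norm)

    p_states = joint.sum(axis=0)
    p_presence = float(joint[1].sum())
    confidence = float(p_states[1:].max())
    report = "seen" if p_presence > report_threshold else "unseen"
    return PosteriorBundle(p_presence=p_presence, p_states=p_states, confidence=confidence, report=report)
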