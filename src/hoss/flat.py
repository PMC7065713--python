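"""Flat (non-hierarchical) signal-detection comparator.

Here "absent" is just one more stimulus class in a single-level Bayesian
classifier over ``N+1`` classes with the same Gaussian emissions as the
hierarchical model. The contrast with the hierarchical observer is purely
architectural: evidence handling is identical, only the prior structure
and the presence query differ. With matched priors the two models produce
identical state posteriors — which is exactly why the hierarchical
model's asymmetric ignition pattern cannot be attributed to the
likelihoods.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (
    ModelSpec,
    PosteriorBundle,
    SpecValidationError,
    _as_float_array,
    categorical_kl,
)

__all__ = ["FlatSpec", "flat_posterior", "flat_infer", "flat_belief_update"]


@dataclass(frozen=True)
class FlatSpec:
    """Single-level classifier spec: shared emissions, one flat prior.

    ``means`` and ``covariance`` follow the same convention as
    :class:`~hoss.model.ModelSpec` (column 0 = absent class). ``prior``
    is a length ``N+1`` probability vector over all classes, absent
    first.
    """

    means: np.ndarray
    covariance: np.ndarray
    prior: np.ndarray
    state_labels: tuple[str, ...] = ()
    _emission: ModelSpec = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        prior = _as_float_array(self.prior, "prior", 1)
        means = _as_float_array(self.means, "means", 2)
        n_classes = means.shape[1]
        if prior.shape != (n_classes,):
            raise SpecValidationError(
                f"prior: expected length {n_classes} (one entry per class incl. absent), got {prior.shape}"
            )
        if np.any(prior < 0):
            raise SpecValidationError("prior: entries must be nonnegative")
        if abs(prior.sum() - 1.0) > 1e-12:
            raise SpecValidationError(f"prior: must sum to 1 within 1e-12, got {prior.sum()!r}")

        # Reuse the hierarchical spec for emission validation and the
        # shared log-likelihood machinery; its own priors are irrelevant
        # here, only the Gaussian emissions are borrowed.
        p_absent = float(prior[0])
        if p_absent < 1.0:
            content = prior[1:] / (1.0 - p_absent)
        else:
            content = np.full(n_classes - 1, 1.0 / (n_classes - 1))
        emission = ModelSpec(
            means=means,
            covariance=self.covariance,
            prior_presence=1.0 - p_absent,
            prior_content_given_presence=content / content.sum(),
            state_labels=self.state_labels,
        )
        prior = np.ascontiguousarray(prior)
        prior.setflags(write=False)
        object.__setattr__(self, "means", emission.means)
        object.__setattr__(self, "covariance", emission.covariance)
        object.__setattr__(self, "prior", prior)
        object.__setattr__(self, "state_labels", emission.state_labels)
        object.__setattr__(self, "_emission", emission)

    @property
    def n_states(self) -> int:
        return self.means.shape[1] - 1

    @property
    def feature_dim(self) -> int:
        return self.means.shape[0]

    def with_precision(self, lam: float) -> "FlatSpec":
        """Scale sensory precision: replace Sigma with Sigma / lam."""
        if not lam > 0:
            raise ValueError(f"precision multiplier must be positive, got {lam}")
        return FlatSpec(
            means=self.means,
            covariance=self.covariance / float(lam),
            prior=self.prior,
            state_labels=self.state_labels,
        )


def flat_posterior(spec: FlatSpec, x) -> np.ndarray:
    """Single-level Bayes rule over all ``N+1`` classes; sums to 1."""
    x = spec._emission.validate_sample(x)
    return _flat_posterior_batch(spec, x[None, :])[0]


def _flat_posterior_batch(spec: FlatSpec, x_batch: np.ndarray) -> np.ndarray:
    from scipy.special import logsumexp

    from .model import _log_likelihood_matrix

    log_lik = _log_likelihood_matrix(spec._emission, x_batch)
    with np.errstate(divide="ignore"):
        log_prior = np.log(spec.prior)
    log_joint = log_prior[None, :] + log_lik
    log_post = log_joint - logsumexp(log_joint, axis=1, keepdims=True)
    return np.exp(log_post)


def flat_infer(
    spec: FlatSpec,
    x,
    report_threshold: float = 0.5,
    report_rule: str = "absent_below_threshold",
) -> PosteriorBundle:
    """Classify one sample with the flat model and read out a report.

    The flat architecture has no awareness variable, so a report rule
    must be imposed. ``"absent_below_threshold"`` (default) reports seen
    iff ``P(absent|x) < report_threshold``, mirroring the hierarchical
    threshold on ``1 - P(absent)``; ``"argmax"`` reports seen iff the
    most probable class is not the absent class.
    """
    if not 0.0 < report_threshold < 1.0:
        raise ValueError(f"report_threshold must lie in (0, 1), got {report_threshold}")
    p = flat_posterior(spec, x)
    if report_rule == "absent_below_threshold":
        seen = p[0] < report_threshold
    elif report_rule == "argmax":
        seen = int(np.argmax(p)) != 0
    else:
        raise ValueError(f"unknown report_rule {report_rule!r}")
    return PosteriorBundle(
        p_presence=float(1.0 - p[0]),
        p_states=p,
        confidence=float(p[1:].max()),
        report="seen" if seen else "unseen",
    )


def flat_belief_update(spec: FlatSpec, x) -> float:
    """KL(flat posterior || flat prior) in nats.

    The flat model has a single level, so this is the whole of its
    Bayesian surprise; in the high-precision limit with a uniform prior
    it tends to ``ln(N+1)`` for every class, present or absent — the
    symmetric counterpart to the hierarchical model's seen/unseen
    asymmetry.
    """
    return categorical_kl(flat_posterior(spec, x), spec.prior)
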