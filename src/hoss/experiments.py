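"""Simulation experiments: lattice maps, trial sampling, masking sweep.

Three experiments probe the hierarchical observer:

1. ``grid_map`` evaluates presence posterior, identity confidence and
   both belief updates on a regular 2D feature lattice (the posterior /
   confidence / surprise surfaces).
2. ``sample_trials`` draws seeded Monte-Carlo trials from the model's own
   generative process and runs inference on each.
3. ``masking_sweep`` repeats the trial simulation across a grid of
   sensory-precision multipliers, emulating a backward-masking
   experiment in which longer stimulus-onset asynchrony (SOA) yields
   higher-precision evidence. Report-conditioned mean KL divergences
   expose the ignition asymmetry: large W-level updates follow "seen"
   decisions while A-level updates stay comparatively symmetric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .flat import FlatSpec, _flat_posterior_batch
from .model import BeliefUpdate, ModelSpec, PosteriorBundle, belief_update_batch, infer_batch

__all__ = [
    "GridSpec",
    "TrialRecord",
    "PrecisionSweepResult",
    "DEFAULT_PRECISIONS",
    "grid_map",
    "sample_trials",
    "masking_sweep",
    "summarize_by_report",
    "trials_to_frame",
    "sweep_to_frame",
]

AnySpec = Union[ModelSpec, FlatSpec]

# Precision multipliers for the simulated masking experiment, chosen so
# the seen-rate curve for present-class trials spans near-0 to near-1
# over the sweep (the mechanism — precision rising with SOA — is fixed;
# the values are a simulation-design choice).
DEFAULT_PRECISIONS: tuple[float, ...] = (0.02, 0.05, 0.1, 0.2, 0.5, 1.0, 2.0)


@dataclass(frozen=True)
class GridSpec:
    """Regular 2D lattice in feature space.

    Bounds are inclusive; points are ``lo, lo+step, …`` up to the last
    point not exceeding ``hi`` by more than half a step (guards float
    drift so an exact upper bound is kept).
    """

    x1_min: float
    x1_max: float
    x1_step: float
    x2_min: float
    x2_max: float
    x2_step: float

    def __post_init__(self) -> None:
        for axis in ("x1", "x2"):
            lo = getattr(self, f"{axis}_min")
            hi = getattr(self, f"{axis}_max")
            step = getattr(self, f"{axis}_step")
            if not hi > lo:
                raise ValueError(f"{axis}: upper bound must exceed lower bound")
            if not step > 0:
                raise ValueError(f"{axis}: step must be positive")
        if len(self.axis_points(1)) * len(self.axis_points(2)) > 10**6:
            raise ValueError("grid too large: more than 1e6 lattice points")

    def axis_points(self, axis: int) -> np.ndarray:
        lo = getattr(self, f"x{axis}_min")
        hi = getattr(self, f"x{axis}_max")
        step = getattr(self, f"x{axis}_step")
        n = int(math.floor((hi - lo) / step + 0.5)) + 1
        return lo + step * np.arange(n)

    def lattice(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Returns (x1 points, x2 points, (n1*n2, 2) row-major lattice)."""
        p1 = self.axis_points(1)
        p2 = self.axis_points(2)
        g1, g2 = np.meshgrid(p1, p2, indexing="ij")
        return p1, p2, np.column_stack([g1.ravel(), g2.ravel()])


@dataclass(frozen=True)
class TrialRecord:
    """One simulated trial: generative truth plus inference results."""

    trial_id: int
    lam: float
    true_class: str
    x: np.ndarray
    bundle: PosteriorBundle
    update: BeliefUpdate


@dataclass(frozen=True)
class PrecisionSweepResult:
    """Report-conditioned summary at one precision level.

    Means over an empty report category are ``nan`` (flagged missing,
    with the corresponding count at 0), never silently zero. The
    asymmetry indices are seen-mean minus unseen-mean and are ``nan``
    whenever either category is empty.
    """

    lam: float
    n_per_class: int
    n_seen: int
    n_unseen: int
    p_seen: float
    p_seen_by_class: dict[str, float]
    mean_kl_w_seen: float
    mean_kl_w_unseen: float
    mean_kl_a_seen: float
    mean_kl_a_unseen: float
    asym_w: float
    asym_a: float


def _require_2d(spec: AnySpec) -> None:
    if spec.feature_dim != 2:
        raise ValueError(
            f"feature-space maps are defined for 2D specs only; got feature_dim={spec.feature_dim}"
        )


def grid_map(spec: ModelSpec, grid: GridSpec, report_threshold: float = 0.5) -> pd.DataFrame:
    """Posterior, confidence and surprise surfaces on a 2D lattice.

    Returns one row per lattice point with columns
    ``x1, x2, p_presence, confidence, kl_w, kl_a, on_contour``.
    ``on_contour`` flags lattice points lying on the ``p_presence = 0.5``
    iso-contour: points exactly at 0.5, plus points where the sign of
    ``p_presence - 0.5`` differs from a 4-neighbour (the discrete trace
    of the decision boundary).
    """
    if not isinstance(spec, ModelSpec):
        raise TypeError("grid_map expects the hierarchical ModelSpec")
    _require_2d(spec)
    p1, p2, lattice = grid.lattice()
    p_states, p_presence, confidence, _seen = infer_batch(spec, lattice, report_threshold)
    kl_w, kl_a = belief_update_batch(spec, p_states)

    n1, n2 = len(p1), len(p2)
    diff = (p_presence - report_threshold).reshape(n1, n2)
    sign = np.sign(diff)
    on = sign == 0
    # a sign change to any 4-neighbour marks both sides of the boundary
    flip_x = sign[1:, :] * sign[:-1, :] < 0
    on[1:, :] |= flip_x
    on[:-1, :] |= flip_x
    flip_y = sign[:, 1:] * sign[:, :-1] < 0
    on[:, 1:] |= flip_y
    on[:, :-1] |= flip_y

    return pd.DataFrame(
        {
            "x1": lattice[:, 0],
            "x2": lattice[:, 1],
            "p_presence": p_presence,
            "confidence": confidence,
            "kl_w": kl_w,
            "kl_a": kl_a,
            "on_contour": on.ravel(),
        }
    )


def _class_streams(seed, n_classes: int) -> list[np.random.Generator]:
    """One child generator per class, spawned deterministically.

    Spawning keys the children by index, so adding classes never
    perturbs the draws of earlier classes under the same seed.
    """
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(int(seed))
    return [np.random.default_rng(child) for child in root.spawn(n_classes)]


def _infer_arrays(spec: AnySpec, x_batch: np.ndarray, report_threshold: float, kl_w_mode: str):
    """Dispatch inference over a batch for either architecture.

    For the flat comparator there is no awareness level: the single
    classifier-level KL is recorded as ``kl_w`` and ``kl_a`` is ``nan``;
    "seen" means the absent-class posterior fell below the threshold.
    """
    if isinstance(spec, ModelSpec):
        p_states, p_presence, confidence, seen = infer_batch(spec, x_batch, report_threshold)
        kl_w, kl_a = belief_update_batch(spec, p_states, kl_w_mode)
    else:
        p_states = _flat_posterior_batch(spec, x_batch)
        p_presence = 1.0 - p_states[:, 0]
        confidence = p_states[:, 1:].max(axis=1)
        seen = p_states[:, 0] < report_threshold
        prior = spec.prior
        with np.errstate(divide="ignore"):
            log_prior = np.log(prior)
        terms = np.where(
            p_states > 0,
            p_states * (np.log(np.where(p_states > 0, p_states, 1.0)) - log_prior[None, :]),
            0.0,
        )
        kl_w = np.maximum(terms.sum(axis=1), 0.0)
        kl_a = np.full(len(x_batch), np.nan)
    return p_states, p_presence, confidence, seen, kl_w, kl_a


def sample_trials(
    spec: AnySpec,
    n_per_class: int,
    seed,
    lam: float = 1.0,
    classes: Sequence[int] | None = None,
    report_threshold: float = 0.5,
    kl_w_mode: str = "joint",
) -> list[TrialRecord]:
    """Draw seeded trials from each class Gaussian and infer each one.

    ``lam`` scales precision for both generation and inference (the
    observer knows the true noise level). ``classes`` optionally
    restricts which true classes are sampled (indices into
    ``0 = absent, 1 … N = content``); each class keeps its own random
    substream, so restricting classes does not change the draws of the
    classes kept. Records are ordered class-major, draw-minor, which
    makes runs bit-for-bit reproducible for a given seed.
    """
    if n_per_class < 1:
        raise ValueError(f"n_per_class must be >= 1, got {n_per_class}")
    scaled = spec.with_precision(lam)
    n_classes = spec.means.shape[1]
    idx = list(range(n_classes)) if classes is None else sorted(set(int(c) for c in classes))
    if any(c < 0 or c >= n_classes for c in idx):
        raise ValueError(f"class indices must lie in [0, {n_classes - 1}]")

    streams = _class_streams(seed, n_classes)
    chol = np.linalg.cholesky(np.asarray(scaled.covariance))

    xs, labels = [], []
    for c in idx:
        z = streams[c].standard_normal((n_per_class, spec.feature_dim))
        xs.append(scaled.means[:, c][None, :] + z @ chol.T)
        labels.extend([spec.state_labels[c]] * n_per_class)
    x_batch = np.vstack(xs)

    p_states, p_presence, confidence, seen, kl_w, kl_a = _infer_arrays(
        scaled, x_batch, report_threshold, kl_w_mode
    )

    records = []
    for i in range(len(x_batch)):
        records.append(
            TrialRecord(
                trial_id=i,
                lam=float(lam),
                true_class=labels[i],
                x=x_batch[i],
                bundle=PosteriorBundle(
                    p_presence=float(p_presence[i]),
                    p_states=p_states[i],
                    confidence=float(confidence[i]),
                    report="seen" if seen[i] else "unseen",
                ),
                update=BeliefUpdate(kl_w=float(kl_w[i]), kl_a=float(kl_a[i])),
            )
        )
    return records


def summarize_by_report(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    """Mean belief updates split by the model's own report.

    Conditioning is purely on the report: misclassified absent-class
    trials pool into "seen" and missed stimuli into "unseen". An empty
    report category yields ``n = 0`` and ``nan`` means.
    """
    if len(trials) == 0:
        raise ValueError("summarize_by_report requires a non-empty trial list")
    rows = []
    for report in ("seen", "unseen"):
        sel = [t for t in trials if t.bundle.report == report]
        if sel:
            kw = float(np.mean([t.update.kl_w for t in sel]))
            ka = float(np.mean([t.update.kl_a for t in sel]))
        else:
            kw = ka = float("nan")
        rows.append({"report": report, "n": len(sel), "mean_kl_w": kw, "mean_kl_a": ka})
    return pd.DataFrame(rows)


def masking_sweep(
    spec: AnySpec,
    precisions: Sequence[float] = DEFAULT_PRECISIONS,
    n_per_class: int = 2000,
    seed: int = 0,
    kl_w_mode: str = "joint",
    classes: Sequence[int] | None = None,
    report_threshold: float = 0.5,
    return_trials: bool = False,
):
    """Simulated masking experiment across sensory-precision levels.

    For each precision multiplier ``lam`` (a proxy for SOA), both the
    generative covariance and the observer's covariance become
    ``Sigma / lam``; trials are drawn from every class, inferred, and
    aggregated by report. Returns a list of
    :class:`PrecisionSweepResult` (and, with ``return_trials=True``, the
    per-level trial lists). A level at which one report category is
    empty carries ``nan`` means for that category; the sweep continues.
    """
    precisions = [float(l) for l in precisions]
    if any(l <= 0 for l in precisions):
        raise ValueError("all precision multipliers must be positive")
    root = np.random.SeedSequence(int(seed))
    level_seeds = root.spawn(len(precisions))

    results: list[PrecisionSweepResult] = []
    all_trials: list[list[TrialRecord]] = []
    for lam, level_seed in zip(precisions, level_seeds):
        trials = sample_trials(
            spec,
            n_per_class,
            level_seed,
            lam=lam,
            classes=classes,
            report_threshold=report_threshold,
            kl_w_mode=kl_w_mode,
        )
        seen = [t for t in trials if t.bundle.report == "seen"]
        unseen = [t for t in trials if t.bundle.report == "unseen"]

        def _mean(vals):
            return float(np.mean(vals)) if len(vals) else float("nan")

        mw_s = _mean([t.update.kl_w for t in seen])
        mw_u = _mean([t.update.kl_w for t in unseen])
        ma_s = _mean([t.update.kl_a for t in seen])
        ma_u = _mean([t.update.kl_a for t in unseen])

        by_class: dict[str, float] = {}
        for label in dict.fromkeys(t.true_class for t in trials):
            cls = [t for t in trials if t.true_class == label]
            by_class[label] = float(np.mean([t.bundle.report == "seen" for t in cls]))

        results.append(
            PrecisionSweepResult(
                lam=lam,
                n_per_class=n_per_class,
                n_seen=len(seen),
                n_unseen=len(unseen),
                p_seen=len(seen) / len(trials),
                p_seen_by_class=by_class,
                mean_kl_w_seen=mw_s,
                mean_kl_w_unseen=mw_u,
                mean_kl_a_seen=ma_s,
                mean_kl_a_unseen=ma_u,
                asym_w=mw_s - mw_u,
                asym_a=ma_s - ma_u,
            )
        )
        if return_trials:
            all_trials.append(trials)

    if return_trials:
        return results, all_trials
    return results


def trials_to_frame(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    """Flatten trial records to the trial CSV schema.

    Columns: ``trial_id, lambda, true_class, x1 … xM, p_presence,
    confidence, report, kl_w, kl_a``.
    """
    m = len(trials[0].x) if trials else 2
    cols: dict[str, list] = {
        "trial_id": [t.trial_id for t in trials],
        "lambda": [t.lam for t in trials],
        "true_class": [t.true_class for t in trials],
    }
    for j in range(m):
        cols[f"x{j + 1}"] = [float(t.x[j]) for t in trials]
    cols["p_presence"] = [t.bundle.p_presence for t in trials]
    cols["confidence"] = [t.bundle.confidence for t in trials]
    cols["report"] = [t.bundle.report for t in trials]
    cols["kl_w"] = [t.update.kl_w for t in trials]
    cols["kl_a"] = [t.update.kl_a for t in trials]
    return pd.DataFrame(cols)


def sweep_to_frame(results: Sequence[PrecisionSweepResult]) -> pd.DataFrame:
    """Flatten sweep summaries to the sweep CSV schema."""
    return pd.DataFrame(
        {
            "lambda": [r.lam for r in results],
            "n_seen": [r.n_seen for r in results],
            "n_unseen": [r.n_unseen for r in results],
            "p_seen": [r.p_seen for r in results],
            "mean_kl_w_seen": [r.mean_kl_w_seen for r in results],
            "mean_kl_w_unseen": [r.mean_kl_w_unseen for r in results],
            "mean_kl_a_seen": [r.mean_kl_a_seen for r in results],
            "mean_kl_a_unseen": [r.mean_kl_a_unseen for r in results],
            "asym_w": [r.asym_w for r in results],
            "asym_a": [r.asym_a for r in results],
        }
    )
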