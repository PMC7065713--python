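"""Config loading, packaged parameter sets, CSV writers and run manifests.

Spec files are flat YAML (or JSON) mappings:

.. code-block:: yaml

    n_states: 2
    feature_dim: 2
    means:            # one mean vector per class, absent (w0) first
      - [0.5, 0.5]
      - [1.5, 0.5]
      - [0.5, 1.5]
    covariance:       # row-major M x M
      - [1.0, 0.0]
      - [0.0, 1.0]
    prior_presence: 0.5
    prior_content_given_presence: [0.5, 0.5]
    state_labels: [absent, w1, w2]

A ``flat_prior`` key switches the file to the single-level comparator
(:class:`~hoss.flat.FlatSpec`); an optional ``precision_grid`` key
supplies default precision multipliers for the masking sweep. Every
output CSV is paired with a JSON run manifest recording the resolved
config, seed, package version and SHA-256 content hashes, so any output
is reproducible from its manifest alone.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from dataclasses import dataclass, field as _field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .flat import FlatSpec
from .model import ModelSpec, SpecValidationError

__all__ = [
    "load_spec",
    "load_spec_dict",
    "load_packaged_spec",
    "packaged_spec_names",
    "read_precision_grid",
    "write_table",
    "RunManifest",
    "CSV_SCHEMAS",
]

CSV_SCHEMAS = {
    "grid": ["x1", "x2", "p_presence", "confidence", "kl_w", "kl_a", "on_contour"],
    "trials": ["trial_id", "lambda", "true_class", "p_presence", "confidence", "report", "kl_w", "kl_a"],
    "sweep": [
        "lambda",
        "n_seen",
        "n_unseen",
        "p_seen",
        "mean_kl_w_seen",
        "mean_kl_w_unseen",
        "mean_kl_a_seen",
        "mean_kl_a_unseen",
        "asym_w",
        "asym_a",
    ],
}

_REQUIRED_KEYS = ("n_states", "feature_dim", "means", "covariance")
_KNOWN_KEYS = set(_REQUIRED_KEYS) | {
    "prior_presence",
    "prior_content_given_presence",
    "state_labels",
    "flat_prior",
    "precision_grid",
}


def _read_mapping(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"spec file not found: {path}")
    text = path.read_text(encoding="utf-8")
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise SpecValidationError(f"spec file {path} must contain a mapping at top level")
    return data


def load_spec_dict(config: dict) -> ModelSpec | FlatSpec:
    """Build a validated spec from a parsed config mapping."""
    unknown = set(config) - _KNOWN_KEYS
    if unknown:
        raise SpecValidationError(f"unknown config keys: {sorted(unknown)}")
    for key in _REQUIRED_KEYS:
        if key not in config:
            raise SpecValidationError(f"{key}: missing required key")

    means_rows = np.asarray(config["means"], dtype=float)
    if means_rows.ndim != 2:
        raise SpecValidationError("means: expected a list of class mean vectors")
    means = means_rows.T  # config lists one vector per class; model stores classes as columns
    n, m = int(config["n_states"]), int(config["feature_dim"])
    if means.shape != (m, n + 1):
        raise SpecValidationError(
            f"means: expected {n + 1} vectors of length {m} "
            f"(declared n_states={n}, feature_dim={m}), got {means_rows.shape[0]} of length {means_rows.shape[1]}"
        )
    labels = tuple(config.get("state_labels", ()))

    if "flat_prior" in config:
        return FlatSpec(
            means=means,
            covariance=np.asarray(config["covariance"], dtype=float),
            prior=np.asarray(config["flat_prior"], dtype=float),
            state_labels=labels,
        )

    for key in ("prior_presence", "prior_content_given_presence"):
        if key not in config:
            raise SpecValidationError(f"{key}: missing required key")
    return ModelSpec(
        means=means,
        covariance=np.asarray(config["covariance"], dtype=float),
        prior_presence=config["prior_presence"],
        prior_content_given_presence=np.asarray(config["prior_content_given_presence"], dtype=float),
        state_labels=labels,
    )


def load_spec(path) -> ModelSpec | FlatSpec:
    """Load and validate a spec file (YAML or JSON).

    Raises :class:`~hoss.model.SpecValidationError` naming the offending
    field on any invariant violation.
    """
    return load_spec_dict(_read_mapping(path))


def read_precision_grid(path) -> list[float] | None:
    """Return the optional ``precision_grid`` list from a spec file."""
    grid = _read_mapping(path).get("precision_grid")
    return [float(v) for v in grid] if grid is not None else None


def packaged_spec_names() -> list[str]:
    """Names of the parameter sets shipped with the package."""
    root = resources.files("hoss") / "specs"
    return sorted(p.name[: -len(".yaml")] for p in root.iterdir() if p.name.endswith(".yaml"))


def load_packaged_spec(name: str) -> ModelSpec | FlatSpec:
    """Load a packaged parameter set by name (see :func:`packaged_spec_names`).

    Shipped sets:

    - ``near_threshold_2d`` — two content classes close to the absent
      class (means 1.0 apart at unit noise); the regime for posterior /
      confidence maps where detection is genuinely uncertain.
    - ``gratings_2d`` — two well-separated "grating tilt" classes
      (means 3.5 from the absent class); the discrimination space used
      for the masking sweep.
    - ``masking_sweep`` — the gratings emissions plus the default
      ``precision_grid`` for the simulated masking experiment.
    - ``gratings_2d_flat`` — the same emissions under the flat
      single-level comparator with a uniform three-class prior.
    """
    res = resources.files("hoss") / "specs" / f"{name}.yaml"
    if not res.is_file():
        raise FileNotFoundError(f"no packaged spec named {name!r}; available: {packaged_spec_names()}")
    return load_spec_dict(yaml.safe_load(res.read_text(encoding="utf-8")))


def packaged_precision_grid(name: str = "masking_sweep") -> list[float] | None:
    res = resources.files("hoss") / "specs" / f"{name}.yaml"
    grid = yaml.safe_load(res.read_text(encoding="utf-8")).get("precision_grid")
    return [float(v) for v in grid] if grid is not None else None


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record for one run: config + seed fully determine output."""

    config: dict
    seed: int | None = None
    version: str = __version__
    created: str = _field(default_factory=lambda: _dt.datetime.now(_dt.timezone.utc).isoformat())
    outputs: list[dict] = _field(default_factory=list)

    def add_output(self, path) -> None:
        path = Path(path)
        entry = {"path": path.name, "sha256": _sha256(path), "bytes": path.stat().st_size}
        self.outputs.append(entry)

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "seed": self.seed,
            "version": self.version,
            "created": self.created,
            "outputs": self.outputs,
        }

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n", encoding="utf-8")

    @classmethod
    def read(cls, path) -> "RunManifest":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            config=data["config"],
            seed=data["seed"],
            version=data["version"],
            created=data["created"],
            outputs=data["outputs"],
        )


def write_table(frame: pd.DataFrame, path, schema: str | None = None, manifest: RunManifest | None = None) -> Path:
    """Write a CSV deterministically (UTF-8, '.' decimal, header row).

    ``schema`` names one of the declared CSV layouts and is checked
    against the frame's columns (the trials schema additionally allows
    the ``x1 … xM`` feature columns). Byte-identical output for
    identical frames; the manifest, if given, records the file hash.
    """
    if schema is not None:
        expected = CSV_SCHEMAS[schema]
        cols = [c for c in frame.columns if not (schema == "trials" and c.startswith("x") and c[1:].isdigit())]
        if cols != expected:
            raise ValueError(f"columns {list(frame.columns)} do not match declared schema {schema!r}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, lineterminator="\n", encoding="utf-8")
    if manifest is not None:
        manifest.add_output(path)
    return path
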