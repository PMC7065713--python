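import numpy as np
import pytest

from hoss import ModelSpec, load_packaged_spec


@pytest.fixture(scope="session")
def near_threshold_spec() -> ModelSpec:
    """Two content classes one noise-SD from the absent class, flat priors."""
    return load_packaged_spec("near_threshold_2d")


@pytest.fixture(scope="session")
def gratings_spec() -> ModelSpec:
    """Well-separated two-class discrimination space, flat priors."""
    return load_packaged_spec("gratings_2d")


def random_spec(rng: np.random.Generator, n: int | None = None, m: int | None = None) -> ModelSpec:
    """A random valid model spec with PD covariance and proper priors."""
    n = n if n is not None else int(rng.integers(1, 6))
    m = m if m is not None else int(rng.integers(1, 5))
    means = rng.normal(scale=3.0, size=(m, n + 1))
    a = rng.normal(size=(m, m))
    cov = a @ a.T + 0.3 * np.eye(m)
    pw = rng.dirichlet(np.ones(n))
    pw = pw / pw.sum()
    return ModelSpec(
        means=means,
        covariance=cov,
        prior_presence=float(rng.uniform(0.05, 0.95)),
        prior_content_given_presence=pw,
    )
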