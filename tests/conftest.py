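import numpy as np
import pytest
from hypothesis import settings

from facoda import GeneratorConfig, apply_exclusions, generate

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def cohort():
    """Moderate synthetic cohort shared across model tests."""
    return generate(GeneratorConfig(n=2500, seed=42, n_pilot=20_000))


@pytest.fixture(scope="session")
def kept(cohort):
    retained, _ = apply_exclusions(cohort)
    return retained


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)


def random_compositions(rng, n, d, kappa=100.0):
    """Strictly positive random compositions, closed to kappa."""
    x = np.exp(rng.normal(0.0, 1.0, size=(n, d)))
    return kappa * x / x.sum(axis=1, keepdims=True)
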