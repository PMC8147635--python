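import numpy as np
import pytest

from breathprint.synthetic import (
    GeneratorConfig,
    generate_cohort,
    generate_worked_fixture,
)


@pytest.fixture(scope="session")
def worked_cohort():
    """Deterministic 12-participant cohort with a clearly separable effect."""
    return generate_worked_fixture()


@pytest.fixture(scope="session")
def small_cohort():
    """Small mixed cohort for I/O and pipeline plumbing tests."""
    cfg = GeneratorConfig(n_cases=5, n_controls=5, seed=7)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort at the default study conditions (49 cases / 35 controls)."""
    return generate_cohort(GeneratorConfig(seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
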