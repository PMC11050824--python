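import warnings

import numpy as np
import pytest

from lsirm import (
    GeneratorConfig,
    ModelConfig,
    RunConfig,
    align_posterior,
    fit_lsirm,
    simulate_lsirm,
    simulate_multifactor,
)

warnings.filterwarnings("ignore", message="some persons have all-0")
warnings.filterwarnings("ignore", message="some items have all-0")


@pytest.fixture(scope="session")
def recovery_run():
    """One seeded parameter-recovery fit: P=300, I=30, gamma=2, clustered items."""
    cfg = GeneratorConfig(n_persons=300, n_items=30, regime="lsirm", gamma=2.0, seed=2)
    truth = simulate_lsirm(cfg)
    samples = fit_lsirm(truth.responses, ModelConfig(), RunConfig(seed=2))
    aligned = align_posterior(samples)
    return truth, samples, aligned


@pytest.fixture(scope="session")
def multifactor_run():
    """Misspecified-unidimensionality scenario: 7 correlated factors x 8 items."""
    cfg = GeneratorConfig(n_persons=800, n_items=56, regime="multifactor", seed=7)
    truth = simulate_multifactor(cfg)
    samples = fit_lsirm(truth.responses, ModelConfig(), RunConfig(seed=7))
    aligned = align_posterior(samples)
    return truth, samples, aligned


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
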