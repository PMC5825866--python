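import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from microlens import CompendiumSimConfig, ExpressionMatrix, simulate_compendium

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture
def tiny_counts() -> ExpressionMatrix:
    data = pd.DataFrame(
        {"s1": [1.0, 1.0, 2.0], "s2": [10.0, 0.0, 30.0]},
        index=pd.Index(["gA", "gB", "gC"], name="gene"),
    )
    return ExpressionMatrix(data, unit="counts")


@pytest.fixture(scope="session")
def noiseless_sim():
    """10 tissues x 1000 genes, 50 disjoint planted markers each, no noise."""
    cfg = CompendiumSimConfig(
        n_tissues=10, n_genes=1000, markers_per_tissue=50,
        marker_elevation=10.0, noise_sd=0.0, seed=11,
    )
    return simulate_compendium(cfg)


@pytest.fixture(scope="session")
def small_noisy_sim():
    """Small noisy compendium shared by identity tests."""
    cfg = CompendiumSimConfig(
        n_tissues=8, n_genes=800, markers_per_tissue=40,
        marker_elevation=10.0, noise_sd=0.5, seed=5,
    )
    return simulate_compendium(cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
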