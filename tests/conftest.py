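import numpy as np
import pandas as pd
import pytest

from intgen.io import CountMatrix
from intgen.simulate import SimConfig, simulate_expression


@pytest.fixture
def tiny_counts() -> CountMatrix:
    counts = pd.DataFrame(
        {"s1": [10, 0, 5], "s2": [20, 4, 1]},
        index=pd.Index(["g1", "g2", "g3"], name="feature"),
    )
    meta = pd.DataFrame(
        {"group": ["tumor", "control"]}, index=pd.Index(["s1", "s2"], name="sample")
    )
    return CountMatrix(counts, meta)


@pytest.fixture(scope="session")
def planted_expression():
    """Medium simulated bundle reused across recovery tests."""
    cfg = SimConfig(
        n_genes=1000,
        n_samples_per_group=20,
        n_modules=2,
        module_size=50,
        de_fraction=0.2,
        seed=42,
    )
    cm, truth = simulate_expression(cfg)
    return cfg, cm, truth


@pytest.fixture(scope="session")
def planted_modules():
    """Two planted 50-gene modules over 300 background genes, no DE signal."""
    cfg = SimConfig(
        n_genes=400,
        n_samples_per_group=20,
        n_modules=2,
        module_size=50,
        de_fraction=0.0,
        latent_factor_sd=0.8,
        seed=42,
    )
    cm, truth = simulate_expression(cfg)
    return cfg, cm, truth
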