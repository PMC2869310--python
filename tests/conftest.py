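import warnings

import numpy as np
import pytest

from costex.model import GeneModel
from costex.synth import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def gene5050() -> GeneModel:
    """Reference gene: X0=50, k=0.01, M=100 (cost at optimum = 1)."""
    return GeneModel.calibrated(50.0, k=0.01, M=100.0)


@pytest.fixture(scope="session")
def small_dataset():
    """One full synthetic dataset shared across tests (n=1500, seed=11)."""
    cfg = GeneratorConfig(n_genes=1500, seed=11)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return cfg, generate_dataset(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
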