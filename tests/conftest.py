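import numpy as np
import pytest

from frbayes import (
    Dataset,
    MCMCConfig,
    ModelKind,
    Params,
)
from frbayes.synthetic import default_design, reference_datasets, simulate_dataset


@pytest.fixture(scope="session")
def fast_mcmc() -> MCMCConfig:
    """Short chain adequate for these 2-3 parameter posteriors."""
    return MCMCConfig(iterations=6000, burn_in=2000, seed=11, log_interval=0)


@pytest.fixture(scope="session")
def h2_params() -> Params:
    """Single-predator reference estimates (attack rate, handling time)."""
    return Params(a=0.464, th=0.220)


@pytest.fixture(scope="session")
def p1_dataset(h2_params) -> Dataset:
    """Synthetic single-predator experiment at the reference estimates."""
    return simulate_dataset(ModelKind.H2, h2_params, default_design(1), seed=7)


@pytest.fixture(scope="session")
def reference_data() -> dict[int, Dataset]:
    return reference_datasets()


def random_params(rng: np.random.Generator) -> Params:
    """Parameter draw spanning the experimentally plausible range."""
    return Params(
        a=rng.uniform(0.05, 1.0),
        th=rng.uniform(0.0, 0.6),
        c=rng.uniform(0.0, 0.5),
        m=rng.uniform(0.0, 0.5),
    )
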