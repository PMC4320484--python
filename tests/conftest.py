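import numpy as np
import pandas as pd
import pytest

from timeomics.synthetic import DesignSpec, SimParams, TruthConfig, generate_design, simulate_dataset


@pytest.fixture(scope="session")
def default_design() -> pd.DataFrame:
    """The 6-timepoint x 4-replicate sampling design."""
    return generate_design(DesignSpec(seed=0))


@pytest.fixture(scope="session")
def small_dataset():
    """A small but fully structured synthetic dataset (shared, read-only)."""
    return simulate_dataset(
        DesignSpec(seed=20),
        SimParams(n_proteins=120, n_metabolites=40, n_physio=4),
        TruthConfig(responder_fraction=0.1, proteins_per_block=6, metabolites_per_block=4),
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
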