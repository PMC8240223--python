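import numpy as np
import pytest

from snpclassify import PopulationModel, simulate_panel


@pytest.fixture(scope="session")
def tiny_panel():
    """Small 3-population panel for fast pipeline-level tests."""
    model = PopulationModel(
        n_populations=3,
        samples_per_population=30,
        n_variants=400,
        divergence=0.2,
        seed=11,
    )
    return simulate_panel(model)


@pytest.fixture(scope="session")
def standard_panel():
    """One realization of the default desk-scale panel (6 x 100 x 5000, F=0.1)."""
    return simulate_panel(PopulationModel(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
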