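import numpy as np
import pytest

from enhancerlink.synthetic import simulate_study


@pytest.fixture(scope="session")
def study():
    """One shared desk-scale synthetic study (seed fixed)."""
    return simulate_study(seed=7)


@pytest.fixture(scope="session")
def small_study():
    """A lighter study for pipeline/file round-trip tests."""
    return simulate_study(
        seed=11, n_genes=400, n_enhancers=100, n_cascades=10,
        n_panel=200, n_cohort=120, n_strains=30,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
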