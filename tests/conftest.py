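import numpy as np
import pytest

from docnet import synthetic as syn


@pytest.fixture(scope="session")
def small_parc():
    """Compact 4-network parcellation (FPN/DMN present), 40 nodes."""
    return syn.make_parcellation(
        {"FPN": 10, "DMN": 14, "VIS": 8, "SMN": 8}, spread_mm=15.0, seed=7
    )


@pytest.fixture(scope="session")
def default_parc():
    """Full-size 264-node, 10-network parcellation."""
    return syn.make_parcellation(seed=1)


@pytest.fixture(scope="session")
def tiny_cohort(small_parc):
    """Small planted-effect cohort for fast end-to-end exercises."""
    parc, subjects = syn.simulate_cohort(
        4, 3, 4, parc=small_parc, T=120, seed=11
    )
    return parc, subjects


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
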