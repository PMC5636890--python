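import numpy as np
import pytest

from viropop.synthetic_data import SyntheticDesign, generate_genomes


@pytest.fixture(scope="session")
def small_design():
    return SyntheticDesign(n_genera=2, genomes_per_genus=3, seed=7)


@pytest.fixture(scope="session")
def small_community(small_design):
    """Two genera x three genomes with planted truth (session-shared)."""
    return generate_genomes(small_design)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
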