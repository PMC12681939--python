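import numpy as np
import pytest

from igpkit.simulate import simulate_glycan_db, simulate_proteome, simulate_spectra


@pytest.fixture(scope="session")
def small_proteome():
    return simulate_proteome(15, seed=11)


@pytest.fixture(scope="session")
def glycan_db():
    return simulate_glycan_db(seed=11)


@pytest.fixture(scope="session")
def small_spectra(small_proteome, glycan_db):
    """60 true + 40 confusable noise scans at moderate noise."""
    return simulate_spectra(
        small_proteome, glycan_db, n_true=60, n_noise=40, noise_level=0.5, seed=7
    )


@pytest.fixture(scope="session")
def search_index(small_proteome):
    from igpkit.peptides import build_search_database

    return build_search_database(proteins=small_proteome, decoy_seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
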