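import numpy as np
import pytest

from metafst import BundleConfig, CensusTable, make_recovery_bundle


@pytest.fixture(scope="session")
def small_bundle():
    """A small but complete synthetic study (shared: expensive to build)."""
    return make_recovery_bundle(
        BundleConfig(n_populations=10, n_loci=4, diploids_per_pop=12, n_sites=50),
        seed=11,
    )


@pytest.fixture
def toy_census():
    """Three sites, seven years, with one extinction/recolonisation."""
    return CensusTable(
        ["a", "b", "c"],
        list(range(2000, 2007)),
        np.array(
            [
                [2, 4, 4, 5, 6, 7, 8],
                [1, 1, 0, 0, 1, 2, 3],
                [0, 0, 0, 0, 0, 0, 5],
            ]
        ),
    )
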