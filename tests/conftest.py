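import numpy as np
import pytest

from reefpop.landscape import PermeabilityConfig, build_cost_surface, lc_distance_matrix
from reefpop.synthetic import ArchipelagoSpec, make_archipelago_raster


@pytest.fixture(scope="session")
def archipelago():
    """One connected 60x80 synthetic seascape with 8 reef sites."""
    raster, cells = make_archipelago_raster(ArchipelagoSpec(seed=11))
    return raster, cells


@pytest.fixture(scope="session")
def archipelago_lc(archipelago):
    """Pairwise LC distances between the 8 sites at uniform permeability."""
    raster, cells = archipelago
    surf = build_cost_surface(raster, PermeabilityConfig(1.0, 1.0))
    return lc_distance_matrix(surf, cells)


def random_haplotype_matrix(rng: np.random.Generator, n_max: int = 12, m_max: int = 50):
    """Random binary haplotype x site matrix (polymorphic columns not forced)."""
    n = int(rng.integers(2, n_max + 1))
    m = int(rng.integers(1, m_max + 1))
    return rng.integers(0, 2, size=(n, m)).astype(np.int8)
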