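import numpy as np
import pytest

from mtgvar.genome_data import DRPTable, GenotypePanel, MarkerMap
from mtgvar.synthetic_data import SimulationConfig, simulate_dataset


def make_map(n_markers, n_chrom=1, spacing=50_000):
    per = n_markers // n_chrom
    sizes = [per] * n_chrom
    sizes[-1] += n_markers - per * n_chrom
    chrom = np.concatenate(
        [np.full(s, c + 1, dtype=np.int64) for c, s in enumerate(sizes)]
    )
    pos = np.concatenate([(np.arange(s) + 1) * spacing for s in sizes])
    ids = np.array([f"m{c}_{p}" for c, p in zip(chrom, pos)], dtype=object)
    return MarkerMap(ids, chrom, pos)


def random_panel(rng, n_animals=30, n_markers=20, pop="pop1", p_range=(0.05, 0.5)):
    p = rng.uniform(*p_range, size=n_markers)
    g = rng.binomial(2, p, size=(n_animals, n_markers))
    return GenotypePanel(pop, g, make_map(n_markers))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_panel(rng):
    return random_panel(rng)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Session-scoped toy dataset: 80+80 animals, 120 markers, 3 regions."""
    cfg = SimulationConfig(
        n_animals=(80, 80),
        markers_per_chromosome=120,
        window=40,
        merge_threshold=20,
        seed=77,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def drp_pair(tiny_dataset):
    return tiny_dataset[1]
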