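import numpy as np
import pytest

from oligotyper import SimulationConfig, simulate_pangenome

BASES = "ACGT"


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


@pytest.fixture
def rng():
    return np.random.default_rng(20240921)


@pytest.fixture(scope="session")
def small_pangenome():
    """A compact pangenome shared by tests that only read it."""
    cfg = SimulationConfig(
        n_assemblies=4, background_length=4_000, n_cluster_genes=4,
        n_target_genes=2, gene_length=600, copy_number_range=(2, 6),
        coverage=12.0, error_rate=0.0, pav_probability=0.6, seed=42,
    )
    return simulate_pangenome(cfg)
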