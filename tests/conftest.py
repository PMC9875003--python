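import numpy as np
import pytest

from breedopt.genome import Chromosome, Genome, Population, simulate_founders


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_genome():
    """Two chromosomes, five markers, hand-placed positions."""
    return Genome(
        (
            Chromosome("c1", 1.0, np.array([0.1, 0.5, 0.9])),
            Chromosome("c2", 0.8, np.array([0.2, 0.6])),
        )
    )


@pytest.fixture
def tiny_population(tiny_genome):
    """Three homozygous founders on the tiny genome."""
    dos = np.array(
        [
            [0, 2, 2, 0, 2],
            [2, 0, 2, 2, 0],
            [0, 0, 0, 0, 0],
        ]
    )
    hap = (dos // 2).astype(np.uint8)
    return Population(
        genome=tiny_genome,
        haplotypes=np.stack([hap, hap], axis=1),
        ids=["A", "B", "C"],
    )


@pytest.fixture(scope="session")
def small_founders():
    """Shared 50-individual synthetic founder set (20 markers, 4 chromosomes)."""
    return simulate_founders(50, 4, 20, seed=7)
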