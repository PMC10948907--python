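import numpy as np
import pytest

from ecckit.io_formats import GenomicInterval
from ecckit.synthio import SyntheticConfig, SyntheticGenome, make_genome, plant_circles


@pytest.fixture(scope="session")
def small_genome():
    """A 3 x 40 kb dictionary genome with no annotation, for sequence-level tests."""
    rng = np.random.default_rng(12345)
    bases = np.array(list("ACGT"))
    return SyntheticGenome(
        sequences={
            f"chr{i + 1}": "".join(rng.choice(bases, size=40_000)) for i in range(3)
        }
    )


@pytest.fixture(scope="session")
def planted_world():
    """Default-style synthetic world with a high repeat fraction: genome,
    truth list, and config (seeded, error-free)."""
    cfg = SyntheticConfig(
        seed=7,
        n_circles=60,
        dr_fraction=0.4,
        ir_fraction=0.2,
        deletion_fraction=0.5,
        error_rate=0.0,
    )
    genome = make_genome(cfg)
    truth, genome = plant_circles(genome, cfg)
    return genome, truth, cfg


def random_intervals(rng, n, chroms=("chr1", "chr2"), max_pos=10_000, max_len=500):
    out = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, start + length))
    return out
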