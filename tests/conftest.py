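import numpy as np
import pytest

from nucleoscan.center_model import beta_offset_pmf
from nucleoscan.config import ScanConfig
from nucleoscan.synthetic import SimSpec, genome_for, simulate_reads
from nucleoscan.triangle import WindowPartition


@pytest.fixture(scope="session")
def default_pmf():
    return beta_offset_pmf()


@pytest.fixture(scope="session")
def default_partition():
    return WindowPartition()


@pytest.fixture(scope="session")
def planted():
    """20-nucleosome 50 kb fixture with light background (sparse regime)."""
    spec = SimSpec(
        chrom_length=50_000,
        centers=list(range(2500, 48_000, 2500)),
        reads_per_side=50,
        jitter_sd=5.0,
        background_rate=1e-4,
        seed=7,
    )
    reads, truth = simulate_reads(spec)
    return spec, reads, truth


@pytest.fixture(scope="session")
def planted_genome(planted):
    spec, _, _ = planted
    return genome_for(spec)


@pytest.fixture(scope="session")
def planted_config():
    return ScanConfig(S=5, T=1, seed=7, chunk_interval=20_000)
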