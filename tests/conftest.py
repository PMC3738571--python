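import numpy as np
import pytest

from goatgrass.formats_io import SeqRecord
from goatgrass.synthetic_data import SimConfig, generate_universe


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = "ACGT"[(("ACGT".index(out[i])) + int(rng.integers(1, 4))) % 4]
    return "".join(out)


@pytest.fixture
def rng():
    return np.random.default_rng(1729)


@pytest.fixture(scope="session")
def small_universe():
    """A compact deterministic universe shared by read-only tests."""
    cfg = SimConfig(
        seed=11,
        n_genes=30,
        gene_len_range=(600, 1000),
        n_species=3,
        paralog_family_rate=0.0,
        reads_per_gene_mean=12.0,
    )
    return cfg, generate_universe(cfg)


def make_records(rng, n, length, prefix="s"):
    return [SeqRecord(f"{prefix}{i:03d}", random_dna(rng, length)) for i in range(n)]
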