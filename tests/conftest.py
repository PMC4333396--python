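import numpy as np
import pytest
from hypothesis import settings

from chromphi.genome_model import ChromTable
from chromphi.synthetic_data import SimulationConfig, simulate_study
from chromphi.tag_signal import TagSet

settings.register_profile("default", derandomize=True, max_examples=100)
settings.load_profile("default")


@pytest.fixture
def chrom_table():
    return ChromTable([("chr1", 10_000), ("chr2", 5_000)])


def make_tagset(chrom_table, rows, sample_id="s", mark="H3K4me3", dedup=True):
    """Build a TagSet from (chrom, pos5, strand) triples."""
    per_chrom = {}
    for chrom in {r[0] for r in rows}:
        sel = [r for r in rows if r[0] == chrom]
        pos = np.array([r[1] for r in sel], dtype=np.int64)
        strand = np.array([0 if r[2] == "+" else 1 for r in sel], dtype=np.int8)
        per_chrom[chrom] = (pos, strand)
    return TagSet.from_arrays(sample_id, mark, chrom_table, per_chrom, dedup=dedup)


@pytest.fixture(scope="session")
def tiny_config():
    return SimulationConfig(
        seed=7,
        n_chrom=1,
        chrom_len=400_000,
        n_genes_per_class={c: 6 for c in ("active", "poised", "repressed", "silent")},
        depth=120_000,
        n_replicates=2,
        gene_length=4_000,
    )


@pytest.fixture(scope="session")
def tiny_study(tiny_config):
    return simulate_study(tiny_config)
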