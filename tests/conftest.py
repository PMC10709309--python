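import numpy as np
import pytest

from stagekit.genome import GeneModel, GenomeLayout, GenomicInterval, Peak
from stagekit.simulate import SyntheticConfig, simulate_all


@pytest.fixture(scope="session")
def small_genome():
    return GenomeLayout({"chr1": 100_000, "chr2": 50_000})


@pytest.fixture
def make_peak():
    def _make(chrom, start, end, name="", score=0.0):
        return Peak(GenomicInterval(chrom, start, end), score, name)

    return _make


@pytest.fixture
def make_gene():
    def _make(gene_id, chrom, tss, strand="+", length=1000):
        if strand == "+":
            span = GenomicInterval(chrom, tss, tss + length, strand)
        else:
            span = GenomicInterval(chrom, tss - length + 1, tss + 1, strand)
        return GeneModel(gene_id, gene_id, chrom, strand, span)

    return _make


@pytest.fixture(scope="session")
def tiny_config():
    """Scaled-down cohort for fast structural tests."""
    return SyntheticConfig(
        seed=11,
        n_chroms=2,
        chrom_length=80_000,
        n_repeats=150,
        n_genes=120,
        n_genomic_genes=20,
        n_peaks_2c_specific=15,
        n_peaks_8c_specific=15,
        n_peaks_shared=10,
        n_background_fragments=6_000,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    return simulate_all(tiny_config)


@pytest.fixture(scope="session")
def default_dataset():
    """One full-size cohort (study conditions) shared across tests."""
    return simulate_all(SyntheticConfig(seed=7))
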