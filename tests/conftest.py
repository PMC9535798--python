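import numpy as np
import pytest

from chipcross.genome import GeneModel, GenomicInterval, TranscriptModel
from chipcross.synthetic import generate_chip, generate_genome


def make_gene(gene_id, chrom, start, end, strand="+", n_tx=1):
    txs = []
    for i in range(n_tx):
        jitter = 50 * i
        if strand == "+":
            iv = GenomicInterval(chrom, start + jitter, end, strand)
        else:
            iv = GenomicInterval(chrom, start, end - jitter, strand)
        txs.append(TranscriptModel(f"{gene_id}.t{i}", iv))
    return GeneModel(gene_id, gene_id, "protein_coding", txs)


@pytest.fixture(scope="session")
def small_genome():
    """300 genes on 2 chromosomes, fixed seed; shared across tests."""
    genes, sizes = generate_genome(
        300, n_chroms=2, chrom_length=3_000_000, seed=11
    )
    return genes, sizes


@pytest.fixture(scope="session")
def small_chip(small_genome):
    genes, sizes = small_genome
    rep1, rep2, classes = generate_chip(
        genes, sizes, factor="factorA", seed=11
    )
    return rep1, rep2, classes


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
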