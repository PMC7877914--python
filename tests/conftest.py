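import numpy as np
import pytest

from tilescreen import guide_design, synthetic_data


@pytest.fixture(scope="session")
def toy_gene():
    """Small 3-exon gene in a random genome (seeded)."""
    genome, gene = synthetic_data.gen_gene_and_genome(
        seed=11, n_exons=3, protein_length=150)
    return genome, gene


@pytest.fixture(scope="session")
def toy_guides(toy_gene):
    genome, gene = toy_gene
    return guide_design.enumerate_guides(gene, genome)


def count_overlapping(text: str, sub: str) -> int:
    """Overlap-aware substring occurrence count (test oracle helper)."""
    count = start = 0
    while True:
        i = text.find(sub, start)
        if i < 0:
            return count
        count += 1
        start = i + 1
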