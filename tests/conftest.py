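import numpy as np
import pytest

from crossde.counting import GenomicInterval, union_exon_model


@pytest.fixture
def rng():
    return np.random.default_rng(20240612)


@pytest.fixture
def small_model():
    """Three non-overlapping single-exon genes on one chromosome."""
    return union_exon_model(
        [
            ("geneA", GenomicInterval("chr1", 100, 250)),
            ("geneB", GenomicInterval("chr1", 300, 400)),
            ("geneC", GenomicInterval("chr2", 0, 500)),
        ]
    )


def random_nonoverlapping_model(rng, n_genes=50, chrom="chr1", exon_len=(120, 400)):
    """Random disjoint multi-exon gene models separated by gaps."""
    records = []
    pos = 0
    for i in range(n_genes):
        gene = f"g{i:03d}"
        for _ in range(int(rng.integers(1, 4))):
            pos += int(rng.integers(50, 200))  # gap
            length = int(rng.integers(*exon_len))
            records.append((gene, GenomicInterval(chrom, pos, pos + length)))
            pos += length
        pos += 300  # inter-gene gap
    return union_exon_model(records)
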