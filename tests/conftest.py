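import numpy as np
import pytest

from mutaccum import MASimConfig, ReferenceGenome, GeneModel, make_reference


@pytest.fixture
def toy_genome():
    """Hand-built 60 bp genome with one CDS per strand.

    plus-strand gene "plusA" at 10–18: codons TTT CAT GGG
    minus-strand gene "minusB" at 31–39: genomic TTAACGCAT, CDS ATG CGT TAA
    """
    seq = (
        "AAAAAAAAA"      # 1-9 intergenic
        "TTTCATGGG"      # 10-18 plusA
        "GAGAGAGAGAGA"   # 19-30 intergenic
        "TTAACGCAT"      # 31-39 minusB (CDS = revcomp = ATGCGTTAA)
        "CCCCCCCCCCCCCCCCCCCCC"  # 40-60 intergenic
    )
    assert len(seq) == 60
    genome = ReferenceGenome({"chr1": seq})
    genes = [
        GeneModel(gene_id="plusA", contig="chr1", start=10, end=18, strand="+"),
        GeneModel(gene_id="minusB", contig="chr1", start=31, end=39, strand="-"),
    ]
    return genome, genes


@pytest.fixture(scope="session")
def sim_reference():
    """Medium synthetic reference shared by simulation-heavy tests."""
    cfg = MASimConfig(
        genome_length=100_000, gene_fraction=0.6, mean_gene_length=300, seed=11
    )
    return make_reference(cfg, np.random.default_rng(11))
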