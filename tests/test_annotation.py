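import numpy as np
import pytest
from Bio.Seq import Seq

from mutaccum import (
    GeneModel,
    MutationRecord,
    ReferenceGenome,
    classify_mutation,
    count_site_opportunities,
    spectrum_class_of,
)
from mutaccum.annotation import Annotator, uniform_spectrum
from mutaccum.core import revcomp

BASES = "ACGT"


def _single_gene_genome(cds: str, strand: str = "+", pad: int = 5):
    """Embed one CDS in poly-A padding so only the gene contributes."""
    genomic = cds if strand == "+" else revcomp(cds)
    seq = "A" * pad + genomic + "A" * pad
    genome = ReferenceGenome({"c": seq})
    gene = GeneModel("g1", "c", pad + 1, pad + len(cds), strand)
    return genome, [gene]


def brute_force_site_counts(cds: str) -> tuple[float, float]:
    """Independent oracle: enumerate all 3 substitutions at every position,
    translating the whole CDS with Biopython, uniform weighting."""
    protein = str(Seq(cds).translate(table=11))
    syn = 0.0
    for i, base in enumerate(cds):
        syn_here = sum(
            1
            for alt in BASES
            if alt != base
            and str(Seq(cds[:i] + alt + cds[i + 1 :]).translate(table=11)) == protein
        )
        syn += syn_here / 3.0
    return syn, len(cds) - syn


class TestClassify:
    def test_third_position_ttt_to_ttc_synonymous(self):
        genome, genes = _single_gene_genome("TTTCATGGG")
        rec = MutationRecord("s", "c", 8, "T", "C")  # third base of TTT
        out = classify_mutation(genome, genes, rec)
        assert out.effect == "synonymous"
        assert out.spectrum_class == "A:T>G:C"
        assert out.region == "coding"
        assert out.genes == ("g1",)

    def test_intergenic_is_noncoding(self):
        genome, genes = _single_gene_genome("TTTCATGGG")
        out = classify_mutation(genome, genes, MutationRecord("s", "c", 2, "A", "G"))
        assert (out.region, out.effect) == ("intergenic", "noncoding")

    def test_intergenic_bps_effect_noncoding(self, toy_genome):
        genome, genes = toy_genome
        out = classify_mutation(genome, genes, MutationRecord("s", "chr1", 5, "A", "G"))
        assert (out.region, out.effect) == ("intergenic", "noncoding")

    def test_reference_mismatch_flagged_not_dropped(self, toy_genome):
        genome, genes = toy_genome  # position 5 holds A
        out = classify_mutation(genome, genes, MutationRecord("s", "chr1", 5, "G", "A"))
        assert out.ref_mismatch
        assert out.region == "intergenic"

    def test_minus_strand_alleles_complemented(self, toy_genome):
        genome, genes = toy_genome
        # minusB CDS = ATG CGT TAA; codon 2 third base maps to genomic 34 (A)
        out = classify_mutation(genome, genes, MutationRecord("s", "chr1", 34, "A", "G"))
        assert out.genes == ("minusB",)
        assert out.effect == "synonymous"  # CGT -> CGC, both Arg

    def test_nonsynonymous_first_position(self, toy_genome):
        genome, genes = toy_genome  # TTT -> CTT is Phe -> Leu
        out = classify_mutation(genome, genes, MutationRecord("s", "chr1", 10, "T", "C"))
        assert out.effect == "nonsynonymous"

    def test_overlap_region_and_full_attribution(self):
        genome, _ = _single_gene_genome("TTTCATGGG")
        genes = [
            GeneModel("g1", "c", 6, 14, "+"),
            GeneModel("g2", "c", 9, 17, "+"),
        ]
        out = classify_mutation(genome, genes, MutationRecord("s", "c", 10, "T", "A"))
        assert out.region == "overlap"
        assert set(out.genes) == {"g1", "g2"}

    def test_position_outside_contig_raises(self, toy_genome):
        genome, genes = toy_genome
        with pytest.raises(IndexError):
            classify_mutation(genome, genes, MutationRecord("s", "chr1", 61, "A", "G"))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_strand_symmetry(self, seed):
        """Classifying on a minus-strand gene equals classifying the reverse
        complement mutation on a plus-strand copy."""
        rng = np.random.default_rng(seed)
        cds = "".join(rng.choice(list(BASES), size=15))
        g_plus, genes_plus = _single_gene_genome(cds, "+")
        g_minus, genes_minus = _single_gene_genome(cds, "-")
        L = len(g_plus.contigs["c"])
        for offset in range(15):
            pos_plus = 6 + offset
            ref = cds[offset]
            for alt in BASES:
                if alt == ref:
                    continue
                out_p = classify_mutation(
                    g_plus, genes_plus, MutationRecord("s", "c", pos_plus, ref, alt)
                )
                pos_minus = L - pos_plus + 1
                out_m = classify_mutation(
                    g_minus, genes_minus,
                    MutationRecord("s", "c", pos_minus, revcomp(ref), revcomp(alt)),
                )
                assert out_p.effect == out_m.effect
                assert out_p.spectrum_class == out_m.spectrum_class


class TestSpectrumClass:
    @pytest.mark.parametrize("ref,alt", [(r, a) for r in BASES for a in BASES if r != a])
    def test_invariant_to_reporting_strand(self, ref, alt):
        assert spectrum_class_of(ref, alt) == spectrum_class_of(
            revcomp(ref), revcomp(alt)
        )

    def test_transition_example(self):
        assert spectrum_class_of("G", "A") == "G:C>A:T"
        assert spectrum_class_of("C", "T") == "G:C>A:T"


class TestSiteOpportunities:
    def test_single_codon_ttt(self):
        genome, genes = _single_gene_genome("TTT")
        opps = count_site_opportunities(genome, genes)
        sites = opps.per_gene["g1"]
        assert sites.syn_sites == pytest.approx(1 / 3)
        assert sites.nonsyn_sites == pytest.approx(8 / 3)

    def test_single_codon_ggg_fourfold(self):
        genome, genes = _single_gene_genome("GGG")
        opps = count_site_opportunities(genome, genes)
        sites = opps.per_gene["g1"]
        assert sites.syn_sites == pytest.approx(1.0)
        assert sites.nonsyn_sites == pytest.approx(2.0)
        # third codon position, genomic coordinate 8 after 5 bp of padding
        assert opps.fourfold_sites == {("c", 8)}

    def test_empty_gene_list_composition_only(self):
        genome = ReferenceGenome({"c": "AATTGGCC"})
        opps = count_site_opportunities(genome, [])
        assert opps.syn_sites == 0
        assert (opps.at_sites, opps.gc_sites) == (4, 4)

    def test_at_gc_partition_of_non_n_genome(self, sim_reference):
        genome, genes = sim_reference
        opps = count_site_opportunities(genome, genes)
        assert opps.at_sites + opps.gc_sites == genome.non_n_length()

    def test_syn_plus_nonsyn_is_three_per_codon(self, sim_reference):
        genome, genes = sim_reference
        opps = count_site_opportunities(genome, genes[:20])
        for g in genes[:20]:
            sites = opps.per_gene[g.gene_id]
            assert sites.syn_sites + sites.nonsyn_sites == pytest.approx(g.length)

    def test_fourfold_sites_are_third_positions(self, sim_reference):
        genome, genes = sim_reference
        opps = count_site_opportunities(genome, genes[:50])
        by_id = {g.gene_id: g for g in genes}
        trees = Annotator(genome, genes[:50])
        for contig, pos in opps.fourfold_sites:
            hits = trees.genes_at(contig, pos)
            assert len(hits) == 1
            g = hits[0]
            offset = pos - g.start if g.strand == "+" else g.end - pos
            assert offset % 3 == 2

    def test_non_multiple_of_three_skipped_with_warning(self):
        genome = ReferenceGenome({"c": "N" * 5 + "TTTC" + "N" * 5})
        genes = [GeneModel("bad", "c", 6, 9, "+")]
        with pytest.warns(UserWarning, match="multiple of 3"):
            opps = count_site_opportunities(genome, genes)
        assert "bad" not in opps.per_gene

    @pytest.mark.parametrize("strand", ["+", "-"])
    @pytest.mark.parametrize("seed", range(6))
    def test_exhaustive_enumeration_oracle(self, seed, strand):
        """Fractional site counts equal whole-protein brute-force enumeration
        for random CDSs up to 30 bp, on both strands."""
        rng = np.random.default_rng(seed)
        n_codons = int(rng.integers(1, 11))
        cds = "".join(rng.choice(list(BASES), size=3 * n_codons))
        genome, genes = _single_gene_genome(cds, strand)
        opps = count_site_opportunities(genome, genes)
        syn, nonsyn = brute_force_site_counts(cds)
        assert opps.per_gene["g1"].syn_sites == pytest.approx(syn)
        assert opps.per_gene["g1"].nonsyn_sites == pytest.approx(nonsyn)

    def test_spectrum_weights_shift_counts(self):
        """A transition-only spectrum makes TTC's third position fully
        synonymous (TTC->TTT is the only transition there)."""
        genome, genes = _single_gene_genome("TTC")
        ts_only = {c: 0.5 for c in ("A:T>G:C", "G:C>A:T")}
        ts_only.update({c: 0.0 for c in ("A:T>T:A", "A:T>C:G", "G:C>C:G", "G:C>T:A")})
        opps = count_site_opportunities(genome, genes, spectrum_weights=ts_only)
        uniform = count_site_opportunities(genome, genes)
        assert opps.per_gene["g1"].syn_sites > uniform.per_gene["g1"].syn_sites
        assert opps.per_gene["g1"].syn_sites + opps.per_gene["g1"].nonsyn_sites == pytest.approx(3.0)
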