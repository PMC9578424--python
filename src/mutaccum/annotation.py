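"""Mutation classification and mutational-opportunity counting.

Base substitutions are classified by genomic region (coding / intergenic /
overlap), codon effect (synonymous / nonsynonymous, strand-aware, bacterial
translation table 11), and collapsed 6-class spectrum. Site opportunities
follow the Nei–Gojobori construction: each codon position contributes the
fraction of its three possible substitutions (optionally weighted by the
mutation spectrum) that are synonymous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from Bio.Data import CodonTable
from intervaltree import IntervalTree

from .core import (
    COMPLEMENT,
    SPECTRUM_CLASSES,
    GeneModel,
    MutationRecord,
    ReferenceGenome,
    revcomp,
    spectrum_class_of,
)

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]

BASES = "ACGT"


def translate_codon(codon: str) -> str:
    """Amino acid for a codon under the bacterial code; '*' for stop."""
    if codon in _TABLE11.stop_codons:
        return "*"
    return _TABLE11.forward_table[codon]


def uniform_spectrum() -> dict[str, float]:
    return {c: 1.0 / len(SPECTRUM_CLASSES) for c in SPECTRUM_CLASSES}


@dataclass
class GeneSites:
    """Fractional synonymous/nonsynonymous site counts for one CDS."""

    gene_id: str
    syn_sites: float
    nonsyn_sites: float
    length: int


@dataclass
class SiteOpportunities:
    """Genome-wide and per-gene mutational site opportunities."""

    per_gene: dict[str, GeneSites]
    at_sites: int
    gc_sites: int
    fourfold_sites: set[tuple[str, int]] = field(default_factory=set)

    @property
    def syn_sites(self) -> float:
        return sum(g.syn_sites for g in self.per_gene.values())

    @property
    def nonsyn_sites(self) -> float:
        return sum(g.nonsyn_sites for g in self.per_gene.values())

    @property
    def nonsyn_syn_ratio(self) -> float:
        return self.nonsyn_sites / self.syn_sites

    def pair_sites(self, spectrum_class: str) -> int:
        """Origin-pair site count for a spectrum class (A:T vs G:C origin)."""
        return self.at_sites if spectrum_class.startswith("A:T") else self.gc_sites


class Annotator:
    """Precomputed gene interval index over a reference genome."""

    def __init__(self, genome: ReferenceGenome, genes: Sequence[GeneModel]):
        self.genome = genome
        self.genes = {g.gene_id: g for g in genes}
        self._trees: dict[str, IntervalTree] = {}
        for g in genes:
            tree = self._trees.setdefault(g.contig, IntervalTree())
            tree[g.start : g.end + 1] = g

    def genes_at(self, contig: str, position: int) -> list[GeneModel]:
        tree = self._trees.get(contig)
        if tree is None:
            return []
        return sorted((iv.data for iv in tree[position]), key=lambda g: g.gene_id)

    # -- per-record classification ------------------------------------------

    def classify(self, record: MutationRecord) -> MutationRecord:
        """Return the record with region, effect, spectrum class and gene
        attribution filled in.

        A reference-allele disagreement with the genome flags the record
        (``ref_mismatch``) instead of dropping it; the codon effect is then
        left unset because the surrounding codon cannot be trusted.
        """
        genome = self.genome
        if record.contig not in genome.contigs:
            raise KeyError(f"contig {record.contig!r} not in reference")
        if not 1 <= record.position <= genome.length(record.contig):
            raise IndexError(
                f"position {record.position} outside contig {record.contig!r}"
            )
        hits = [g for g in self.genes_at(record.contig, record.position) if g.is_cds]
        region = "intergenic" if not hits else ("coding" if len(hits) == 1 else "overlap")
        genome_base = genome.base(record.contig, record.position)
        mismatch = genome_base != record.ref[0]

        spectrum = None
        effect: Optional[str] = None
        if record.is_bps:
            spectrum = spectrum_class_of(record.ref, record.alt)
            if not hits:
                effect = "noncoding"
            elif not mismatch:
                calls = [self._codon_effect(g, record.position, record.alt) for g in hits]
                calls = [c for c in calls if c is not None]
                if calls:
                    effect = "nonsynonymous" if "nonsynonymous" in calls else "synonymous"
        return record.annotated(
            region=region,
            effect=effect,
            spectrum_class=spectrum,
            genes=tuple(g.gene_id for g in hits),
            ref_mismatch=mismatch,
        )

    def _codon_effect(self, gene: GeneModel, position: int, alt: str) -> Optional[str]:
        """Synonymous/nonsynonymous call for a substitution within one CDS."""
        if gene.strand == "+":
            offset = position - gene.start - gene.phase
            alt_cds = alt
        else:
            offset = gene.end - position - gene.phase
            alt_cds = COMPLEMENT[alt]
        if offset < 0:
            return None  # inside the phase-trimmed overhang; no defined codon
        codon_idx, codon_pos = divmod(offset, 3)
        cds = self._cds_sequence(gene)
        codon = cds[3 * codon_idx : 3 * codon_idx + 3]
        if len(codon) < 3 or "N" in codon:
            return None
        mutated = codon[:codon_pos] + alt_cds + codon[codon_pos + 1 :]
        return "synonymous" if translate_codon(mutated) == translate_codon(codon) else "nonsynonymous"

    def _cds_sequence(self, gene: GeneModel) -> str:
        seq = self.genome.slice(gene.contig, gene.start, gene.end)
        if gene.strand == "-":
            seq = revcomp(seq)
        return seq[gene.phase :]


def classify_mutation(
    genome: ReferenceGenome, genes: Sequence[GeneModel], record: MutationRecord
) -> MutationRecord:
    """One-shot classification; build an Annotator for repeated use."""
    return Annotator(genome, genes).classify(record)


def annotate_all(
    genome: ReferenceGenome,
    genes: Sequence[GeneModel],
    records: Iterable[MutationRecord],
) -> list[MutationRecord]:
    ann = Annotator(genome, genes)
    return [ann.classify(r) for r in records]


# -- site-opportunity counting ----------------------------------------------


def _substitution_weight(ref: str, alt: str, weights: Mapping[str, float]) -> float:
    return weights[spectrum_class_of(ref, alt)]


def _codon_syn_fractions(weights: Mapping[str, float]) -> dict[str, tuple[float, float, float]]:
    """For every codon, the weighted synonymous fraction at each position."""
    table: dict[str, tuple[float, float, float]] = {}
    for c1 in BASES:
        for c2 in BASES:
            for c3 in BASES:
                codon = c1 + c2 + c3
                aa = translate_codon(codon)
                fracs = []
                for pos in range(3):
                    syn_w = tot_w = 0.0
                    for alt in BASES:
                        if alt == codon[pos]:
                            continue
                        mutated = codon[:pos] + alt + codon[pos + 1 :]
                        w = _substitution_weight(codon[pos], alt, weights)
                        tot_w += w
                        if translate_codon(mutated) == aa:
                            syn_w += w
                    fracs.append(syn_w / tot_w if tot_w > 0 else 0.0)
                table[codon] = tuple(fracs)
    return table


def _fourfold_codon_prefixes() -> set[str]:
    """Two-base prefixes whose four codons all encode the same amino acid."""
    prefixes = set()
    for c1 in BASES:
        for c2 in BASES:
            aas = {translate_codon(c1 + c2 + b) for b in BASES}
            if len(aas) == 1 and "*" not in aas:
                prefixes.add(c1 + c2)
    return prefixes


def _coverage_counts(genome: ReferenceGenome, genes: Sequence[GeneModel]) -> dict[str, np.ndarray]:
    """Per-contig CDS coverage depth (1-based index; index 0 unused)."""
    cov: dict[str, np.ndarray] = {}
    for contig, seq in genome.contigs.items():
        arr = np.zeros(len(seq) + 2, dtype=np.int32)
        cov[contig] = arr
    for g in genes:
        if not g.is_cds:
            continue
        arr = cov[g.contig]
        arr[g.start] += 1
        arr[g.end + 1] -= 1
    return {c: np.cumsum(a)[: len(genome.contigs[c]) + 1] for c, a in cov.items()}


def count_site_opportunities(
    genome: ReferenceGenome,
    genes: Sequence[GeneModel],
    spectrum_weights: Optional[Mapping[str, float]] = None,
) -> SiteOpportunities:
    """Nei–Gojobori-style fractional syn/nonsyn sites per CDS, genome base
    composition, and the 4-fold degenerate third-position site set.

    Every codon (stop codons included, stop→stop counted synonymous)
    contributes its three positions, each apportioned by the spectrum-weighted
    fraction of substitutions that preserve the encoded amino acid; hence
    syn + nonsyn = 3 × codons for each gene. 4-fold sites covered by more
    than one gene are excluded, since degeneracy in one reading frame does
    not imply neutrality in an overlapping frame. CDSs whose length (after
    phase trimming) is not a multiple of 3 are skipped with a warning.
    """
    weights = dict(spectrum_weights) if spectrum_weights else uniform_spectrum()
    if any(w < 0 for w in weights.values()) or sum(weights.values()) <= 0:
        raise ValueError("spectrum weights must be non-negative and sum to > 0")
    syn_table = _codon_syn_fractions(weights)
    fourfold_prefixes = _fourfold_codon_prefixes()
    coverage = _coverage_counts(genome, genes)

    per_gene: dict[str, GeneSites] = {}
    fourfold: set[tuple[str, int]] = set()
    for g in genes:
        if not g.is_cds:
            continue
        seq = genome.slice(g.contig, g.start, g.end)
        if g.strand == "-":
            seq = revcomp(seq)
        seq = seq[g.phase :]
        if len(seq) % 3 != 0:
            warnings.warn(
                f"gene {g.gene_id}: CDS length {len(seq)} not a multiple of 3; skipped"
            )
            continue
        syn = 0.0
        n_codons = len(seq) // 3
        cov = coverage[g.contig]
        for i in range(n_codons):
            codon = seq[3 * i : 3 * i + 3]
            if "N" in codon:
                continue
            fr = syn_table[codon]
            syn += fr[0] + fr[1] + fr[2]
            if codon[:2] in fourfold_prefixes:
                # genomic coordinate of the codon's third position
                if g.strand == "+":
                    pos = g.start + g.phase + 3 * i + 2
                else:
                    pos = g.end - g.phase - 3 * i - 2
                if cov[pos] == 1:
                    fourfold.add((g.contig, pos))
        total = 3.0 * sum(1 for i in range(n_codons) if "N" not in seq[3 * i : 3 * i + 3])
        per_gene[g.gene_id] = GeneSites(
            gene_id=g.gene_id, syn_sites=syn, nonsyn_sites=total - syn, length=g.length
        )

    at = gc = 0
    for seq in genome.contigs.values():
        at += seq.count("A") + seq.count("T")
        gc += seq.count("G") + seq.count("C")
    return SiteOpportunities(
        per_gene=per_gene, at_sites=at, gc_sites=gc, fourfold_sites=fourfold
    )
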