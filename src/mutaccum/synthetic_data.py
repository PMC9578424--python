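"""Generators for every input the pipeline consumes.

Three experimental designs are emulated at desk scale:

* mutation accumulation (MA): replicate lines passed through single-colony
  bottlenecks, ~27.5 cell divisions per daily transfer over 40 transfers,
  so mutations accumulate nearly neutrally — per-line counts are Poisson in
  rate × sites × divisions;
* serial-transfer experimental evolution: 1:1000 daily dilution of a liquid
  culture (~10 doublings per cycle), modelled as deterministic regrowth with
  multinomial (per-locus binomial) resampling at each bottleneck, optional
  positive selection at designated resistance loci, and new mutations
  entering in proportion to the current population size;
* plating assays: replicate CFU counts that are Poisson in EOP × inoculum.

Populations are simulated at a scaled census size (default 10⁵ cells, not
the study-scale ~10¹¹); selection coefficients and mutation supplies are
interpreted at the scaled size. Every generator is bit-reproducible under a
fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .core import (
    COMPLEMENT,
    SPECTRUM_CLASSES,
    GeneModel,
    LineMetadata,
    MutationRecord,
    ReferenceGenome,
)
from .phenotype import PlatingSeries

#: observed control-line spectrum of the MA design this package emulates
DEFAULT_SPECTRUM = {
    "A:T>G:C": 19 / 105,
    "G:C>A:T": 35 / 105,
    "A:T>T:A": 13 / 105,
    "A:T>C:G": 18 / 105,
    "G:C>C:G": 5 / 105,
    "G:C>T:A": 15 / 105,
}

BASES = "ACGT"


def _as_rng(rng: np.random.Generator | int | None, seed: Optional[int]) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    if rng is not None:
        return np.random.default_rng(rng)
    return np.random.default_rng(seed)


@dataclass
class MASimConfig:
    """Mutation-accumulation design parameters.

    Defaults mirror the emulated study: ~27.48 cell divisions per transfer
    over 40 single-colony transfers (T ≈ 1099), 200 replicate lines, a BPS
    rate of 1.45×10⁻¹⁰ and an indel rate of 1.94×10⁻¹¹ per site per
    division, genome GC 50.8% with ~85% coding density. The genome length
    defaults to the E. coli chromosome's 4,641,652 bp; tests use shorter
    genomes with proportionally higher rates.
    """

    genome_length: int = 4_641_652
    gc_fraction: float = 0.508
    gene_fraction: float = 0.85
    mean_gene_length: int = 900
    bps_rate: float = 1.45e-10
    indel_rate: float = 1.94e-11
    spectrum: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SPECTRUM))
    lines: int = 200
    g: float = 27.48
    transfers: int = 40
    group: str = "control"
    sample_prefix: str = "ma"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.lines < 1 or self.transfers < 1:
            raise ValueError("lines and transfers must be ≥ 1")
        if self.bps_rate < 0 or self.indel_rate < 0:
            raise ValueError("rates must be non-negative")
        total = sum(self.spectrum.values())
        if not math.isclose(total, 1.0, rel_tol=1e-6):
            raise ValueError(f"spectrum probabilities sum to {total}, expected 1")

    @property
    def divisions(self) -> float:
        return self.g * self.transfers


@dataclass
class EvoSimConfig:
    """Serial-transfer experimental-evolution parameters (scaled census).

    Defaults follow the emulated regime: 1:1000 daily dilution, ~10
    doublings per cycle, 40 transfers, 12 populations per group. The census
    size is scaled to 10⁵ cells; ``selected_loci`` maps 1-based genomic
    positions (first contig) to selection coefficients, with resistant
    alleles arising at ``locus_mutation_rate`` per replication — illustrative
    values, as the emulated study estimates no selection coefficients.
    """

    population_size: int = 100_000
    bottleneck_fraction: float = 1e-3
    generations_per_cycle: int = 10
    transfers: int = 40
    mutation_rate: float = 0.0  # genome-wide, per site per replication
    selected_loci: dict[int, float] = field(default_factory=dict)
    locus_mutation_rate: float = 1e-4
    populations: int = 12
    detection_threshold: float = 0.05
    initial_frequencies: dict[int, float] = field(default_factory=dict)
    spectrum: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SPECTRUM))
    group: str = "treatment"
    sample_prefix: str = "evo"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0 < self.bottleneck_fraction < 1:
            raise ValueError("bottleneck fraction must be in (0, 1)")
        if any(s < -1 for s in self.selected_loci.values()):
            raise ValueError("selection coefficients must be ≥ −1")
        if self.population_size > 10**6:
            raise ValueError("scaled population size capped at 1e6 for desk runs")


def make_reference(
    config: MASimConfig, rng: np.random.Generator | int | None = None
) -> tuple[ReferenceGenome, list[GeneModel]]:
    """Random single-contig genome with evenly spaced non-overlapping CDSs.

    Gene length is the configured mean rounded down to a multiple of 3; the
    gene count follows from the coding fraction. Strands are drawn at
    random. Deterministic under a fixed seed.
    """
    rng = _as_rng(rng, config.seed)
    L = config.genome_length
    p_gc = config.gc_fraction
    probs = [(1 - p_gc) / 2, p_gc / 2, p_gc / 2, (1 - p_gc) / 2]
    seq = "".join(np.array(list(BASES))[rng.choice(4, size=L, p=probs)])
    genome = ReferenceGenome({"chr1": seq})

    gene_len = max(3, (config.mean_gene_length // 3) * 3)
    n_genes = 0
    if config.gene_fraction > 0:
        n_genes = max(1, round(config.gene_fraction * L / gene_len))
    if n_genes * gene_len > L:
        raise ValueError("gene demands exceed genome length")
    genes: list[GeneModel] = []
    if n_genes:
        gap = (L - n_genes * gene_len) / (n_genes + 1)
        strands = rng.choice(["+", "-"], size=n_genes)
        cursor = 0.0
        width = len(str(n_genes))
        for i in range(n_genes):
            start = int(round(cursor + gap)) + 1
            end = start + gene_len - 1
            genes.append(
                GeneModel(
                    gene_id=f"g{i + 1:0{width}d}",
                    contig="chr1",
                    start=start,
                    end=end,
                    strand=str(strands[i]),
                )
            )
            cursor = end
    return genome, genes


def _base_positions(genome: ReferenceGenome) -> dict[str, list[tuple[str, np.ndarray]]]:
    """Per-base 1-based position arrays, per contig."""
    out: dict[str, list[tuple[str, np.ndarray]]] = {b: [] for b in BASES}
    for contig, seq in genome.contigs.items():
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        for b in BASES:
            positions = np.nonzero(arr == ord(b))[0] + 1
            out[b].append((contig, positions))
    return out


def _draw_site(base_positions, base: str, rng: np.random.Generator) -> tuple[str, int]:
    pools = base_positions[base]
    sizes = np.array([len(p) for _, p in pools])
    if sizes.sum() == 0:
        raise ValueError(f"genome contains no {base} sites")
    k = rng.choice(len(pools), p=sizes / sizes.sum()) if len(pools) > 1 else 0
    contig, positions = pools[k]
    return contig, int(positions[rng.integers(len(positions))])


# orientation pairs per collapsed class: (ref, alt) on each strand
_CLASS_CHANGES = {}
for _cls in SPECTRUM_CLASSES:
    _ref = _cls[0]  # A or G
    _alt = _cls.split(">")[1][0]
    _CLASS_CHANGES[_cls] = ((_ref, _alt), (COMPLEMENT[_ref], COMPLEMENT[_alt]))


def simulate_ma(
    genome: ReferenceGenome,
    genes: Sequence[GeneModel],
    config: MASimConfig,
    rng: np.random.Generator | int | None = None,
) -> tuple[list[MutationRecord], list[LineMetadata]]:
    """Neutral MA mutations: per-line Poisson counts, spectrum-faithful.

    Each mutation draws its collapsed class from the configured spectrum,
    a reporting strand at random, and then a uniform site among positions
    carrying the matching reference base — so realized class proportions are
    unbiased estimates of the configured probabilities regardless of genome
    composition. Mutations are clonal singletons (no within-line
    polymorphism). Refuses configurations whose expected per-line mutation
    count exceeds 10% of the genome (MA sparsity violated).
    """
    rng = _as_rng(rng, config.seed)
    N = genome.non_n_length()
    T = config.divisions
    expected_bps = config.bps_rate * N * T
    if expected_bps > 0.1 * N:
        raise ValueError(
            f"expected {expected_bps:.0f} mutations per line exceeds 10% of the "
            "genome; multi-hit sites would not be negligible"
        )
    base_positions = _base_positions(genome)
    classes = list(config.spectrum)
    class_p = np.array([config.spectrum[c] for c in classes])

    records: list[MutationRecord] = []
    metadata: list[LineMetadata] = []
    width = len(str(config.lines))
    for i in range(config.lines):
        sample = f"{config.sample_prefix}{i + 1:0{width}d}"
        metadata.append(LineMetadata(sample=sample, T=T, N=N, group=config.group))
        for _ in range(rng.poisson(expected_bps)):
            cls = classes[rng.choice(len(classes), p=class_p)]
            ref, alt = _CLASS_CHANGES[cls][rng.integers(2)]
            contig, pos = _draw_site(base_positions, ref, rng)
            records.append(
                MutationRecord(sample=sample, contig=contig, position=pos, ref=ref, alt=alt)
            )
        for _ in range(rng.poisson(config.indel_rate * N * T)):
            records.append(_random_indel(genome, sample, rng))
    return records, metadata


def _random_indel(genome: ReferenceGenome, sample: str, rng: np.random.Generator) -> MutationRecord:
    contig = list(genome.contigs)[rng.integers(len(genome.contigs))]
    seq = genome.contigs[contig]
    pos = int(rng.integers(1, len(seq)))  # anchor with a following base
    anchor = seq[pos - 1]
    if rng.integers(2):  # insertion of one base after the anchor
        return MutationRecord(
            sample=sample, contig=contig, position=pos,
            ref=anchor, alt=anchor + BASES[rng.integers(4)],
        )
    return MutationRecord(  # deletion of the base after the anchor
        sample=sample, contig=contig, position=pos,
        ref=anchor + seq[pos], alt=anchor,
    )


def simulate_evolution(
    genome: ReferenceGenome,
    genes: Sequence[GeneModel],
    config: EvoSimConfig,
    rng: np.random.Generator | int | None = None,
) -> list[MutationRecord]:
    """Wright–Fisher serial-transfer populations; per-locus frequencies.

    Each cycle: ``generations_per_cycle`` doublings of deterministic
    regrowth from the bottleneck (selection updates allele frequencies each
    generation; new mutations enter at rate × current population size),
    then binomial resampling of every segregating site down to the
    bottleneck size — the dominant noise source under 1000-fold dilution.
    Loci evolve independently (no linkage). Returns records for sites whose
    final frequency exceeds the detection threshold.
    """
    rng = _as_rng(rng, config.seed)
    contig = next(iter(genome.contigs))
    L = genome.length(contig)
    N = config.population_size
    Nb = max(1, int(round(N * config.bottleneck_fraction)))
    g = config.generations_per_cycle

    classes = list(config.spectrum)
    class_p = np.array([config.spectrum[c] for c in classes])

    records: list[MutationRecord] = []
    width = len(str(config.populations))
    for p_idx in range(config.populations):
        sample = f"{config.sample_prefix}{p_idx + 1:0{width}d}"
        # selected loci are tracked as scalars; neutral sites as arrays
        sel: dict[int, float] = {
            locus: config.initial_frequencies.get(locus, 0.0)
            for locus in config.selected_loci
        }
        neutral_pos = np.array(
            [p for p in config.initial_frequencies if p not in sel], dtype=np.int64
        )
        neutral_freq = np.array(
            [config.initial_frequencies[p] for p in neutral_pos], dtype=float
        )
        for _cycle in range(config.transfers):
            new_pos: list[np.ndarray] = []
            new_freq: list[np.ndarray] = []
            for t in range(g):
                n_t = min(N, Nb * 2**t)
                # deterministic selection response at selected loci
                for locus, s in config.selected_loci.items():
                    p = sel[locus]
                    if 0.0 < p < 1.0 and s != 0.0:
                        sel[locus] = p * (1 + s) / (1 + p * s)
                    # focused mutation supply at the resistance locus
                    if config.locus_mutation_rate > 0 and sel[locus] < 1.0:
                        k = rng.poisson(config.locus_mutation_rate * n_t * (1 - sel[locus]))
                        if k:
                            sel[locus] = min(1.0, sel[locus] + k / n_t)
                # genome-wide neutral mutation supply
                if config.mutation_rate > 0:
                    k = rng.poisson(config.mutation_rate * n_t * L)
                    if k:
                        new_pos.append(rng.integers(1, L + 1, size=k))
                        new_freq.append(np.full(k, 1.0 / n_t))
            # transfer bottleneck: binomial resampling of every site
            if new_pos:
                neutral_pos = np.concatenate([neutral_pos, *new_pos])
                neutral_freq = np.concatenate([neutral_freq, *new_freq])
            if neutral_pos.size:
                counts = rng.binomial(Nb, np.clip(neutral_freq, 0.0, 1.0))
                keep = counts > 0
                neutral_pos = neutral_pos[keep]
                neutral_freq = counts[keep] / Nb
            for locus in sel:
                if sel[locus] > 0:
                    sel[locus] = rng.binomial(Nb, min(1.0, sel[locus])) / Nb
        # merge duplicate neutral sites (independent lineages at one position)
        if neutral_pos.size:
            uniq, inverse = np.unique(neutral_pos, return_inverse=True)
            summed = np.bincount(inverse, weights=neutral_freq)
            freqs = {int(p): min(1.0, f) for p, f in zip(uniq, summed)}
        else:
            freqs = {}
        for locus, f in sel.items():
            if f > 0:
                freqs[locus] = min(1.0, freqs.get(locus, 0.0) + f)
        for pos, freq in sorted(freqs.items()):
            if freq > config.detection_threshold:
                ref = genome.base(contig, pos)
                alt = _draw_alt(ref, classes, class_p, rng)
                records.append(
                    MutationRecord(
                        sample=sample, contig=contig, position=pos,
                        ref=ref, alt=alt, allele_frequency=freq,
                    )
                )
    return records


def _draw_alt(ref: str, classes, class_p, rng: np.random.Generator) -> str:
    if ref == "N":
        return "A"
    # restrict the spectrum to classes whose origin pair contains ref
    usable, weights = [], []
    for cls, p in zip(classes, class_p):
        for r, a in _CLASS_CHANGES[cls]:
            if r == ref:
                usable.append(a)
                weights.append(p)
    weights = np.array(weights)
    return usable[rng.choice(len(usable), p=weights / weights.sum())]


def simulate_plating(
    true_eop: Mapping[float, float],
    reference_cfu: int,
    replicates: int = 3,
    rng: np.random.Generator | int | None = None,
    seed: Optional[int] = None,
) -> PlatingSeries:
    """Poisson CFU counts per concentration: counts ~ Poisson(EOP × N)."""
    rng = _as_rng(rng, seed)
    if reference_cfu <= 0 or replicates < 1:
        raise ValueError("reference CFU and replicates must be positive")
    concentrations = sorted(true_eop)
    counts = {}
    for conc in concentrations:
        e = true_eop[conc]
        if e < 0:
            raise ValueError(f"EOP at {conc} is negative")
        counts[conc] = [int(c) for c in rng.poisson(e * reference_cfu, size=replicates)]
    return PlatingSeries(
        concentrations=[float(c) for c in concentrations],
        counts={float(c): v for c, v in counts.items()},
        reference_cfu=[reference_cfu] * replicates,
    )
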