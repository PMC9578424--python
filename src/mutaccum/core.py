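"""Shared domain types for mutation-accumulation and experimental-evolution data.

Coordinates are 1-based inclusive throughout, matching VCF and GFF3. The six
collapsed base-substitution classes pair each change with its reverse
complement (A:T>G:C covers A>G and T>C), so a substitution reported from
either strand maps to the same class.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: the two transition classes followed by the four transversion classes
SPECTRUM_CLASSES = (
    "A:T>G:C",
    "G:C>A:T",
    "A:T>T:A",
    "A:T>C:G",
    "G:C>C:G",
    "G:C>T:A",
)
TRANSITION_CLASSES = SPECTRUM_CLASSES[:2]
TRANSVERSION_CLASSES = SPECTRUM_CLASSES[2:]

VALID_ALLELE = set("ACGTN")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def spectrum_class_of(ref: str, alt: str) -> str:
    """Collapsed 6-class label for a single-base substitution.

    The class is keyed by the reference base pair: a G>A call and the
    complementary-strand C>T call both collapse to G:C>A:T.
    """
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        raise ValueError(f"not a base substitution: {ref}>{alt}")
    if ref in "CT":
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
    # ref is now A or G
    label = f"{ref}:{COMPLEMENT[ref]}>{alt}:{COMPLEMENT[alt]}"
    if label not in SPECTRUM_CLASSES:
        raise ValueError(f"unrecognized substitution {ref}>{alt}")
    return label


@dataclass
class ReferenceGenome:
    """Uppercase A/C/G/T/N sequences keyed by contig id, insertion order kept."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        if not self.contigs:
            raise FormatError("reference genome has no contigs")
        for name, seq in self.contigs.items():
            if not seq:
                raise FormatError(f"contig {name!r} is empty")
            bad = set(seq) - VALID_ALLELE
            if bad:
                raise FormatError(f"contig {name!r} has non-ACGTN characters: {sorted(bad)}")

    def length(self, contig: str) -> int:
        return len(self.contigs[contig])

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def non_n_length(self) -> int:
        """Genome length excluding N bases; the site-opportunity denominator."""
        return sum(len(s) - s.count("N") for s in self.contigs.values())

    def base(self, contig: str, position: int) -> str:
        """Reference base at a 1-based position."""
        seq = self.contigs[contig]
        if not 1 <= position <= len(seq):
            raise IndexError(f"position {position} outside contig {contig!r} (length {len(seq)})")
        return seq[position - 1]

    def slice(self, contig: str, start: int, end: int) -> str:
        """Subsequence over a 1-based inclusive interval."""
        return self.contigs[contig][start - 1 : end]


@dataclass(frozen=True)
class GeneModel:
    """One gene/CDS feature; start/end are 1-based inclusive."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    name: str = ""
    is_cds: bool = True
    phase: int = 0

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise FormatError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end}]"
            )
        if self.strand not in "+-":
            raise FormatError(f"gene {self.gene_id}: strand must be + or -")
        if self.phase not in (0, 1, 2):
            raise FormatError(f"gene {self.gene_id}: phase must be 0/1/2")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class MutationRecord:
    """One called mutation from an MA line or an evolved population."""

    sample: str
    contig: str
    position: int
    ref: str
    alt: str
    mclass: str = ""  # BPS / insertion / deletion, derived if empty
    allele_frequency: Optional[float] = None
    region: Optional[str] = None  # coding / intergenic / overlap
    effect: Optional[str] = None  # synonymous / nonsynonymous / noncoding
    spectrum_class: Optional[str] = None
    genes: tuple[str, ...] = ()
    ref_mismatch: bool = False

    def __post_init__(self) -> None:
        self.ref = self.ref.upper()
        self.alt = self.alt.upper()
        for allele, label in ((self.ref, "ref"), (self.alt, "alt")):
            if not allele or set(allele) - VALID_ALLELE:
                raise FormatError(
                    f"{label} allele {allele!r} at {self.contig}:{self.position} "
                    "is not ACGTN"
                )
        if not self.mclass:
            self.mclass = classify_alleles(self.ref, self.alt)
        if self.mclass == "BPS" and (len(self.ref) != 1 or len(self.alt) != 1 or self.ref == self.alt):
            raise ValueError(f"BPS requires distinct single-base alleles: {self.ref}>{self.alt}")
        if self.mclass in ("insertion", "deletion") and self.indel_length < 1:
            raise ValueError(f"indel with zero length difference: {self.ref}>{self.alt}")
        if self.allele_frequency is not None and not 0 <= self.allele_frequency <= 1:
            raise ValueError(f"allele frequency {self.allele_frequency} outside [0, 1]")

    @property
    def is_bps(self) -> bool:
        return self.mclass == "BPS"

    @property
    def indel_length(self) -> int:
        """Inserted/deleted bases, excluding the VCF anchor base."""
        return abs(len(self.alt) - len(self.ref))

    def annotated(self, **kwargs) -> "MutationRecord":
        return replace(self, **kwargs)


def classify_alleles(ref: str, alt: str) -> str:
    if len(ref) == len(alt) == 1:
        if ref == alt:
            raise ValueError(f"ref equals alt ({ref})")
        return "BPS"
    return "insertion" if len(alt) > len(ref) else "deletion"


@dataclass(frozen=True)
class LineMetadata:
    """Per-line experiment bookkeeping: divisions passed and sites analyzed."""

    sample: str
    T: float  # cell divisions experienced by the line
    N: float  # analyzed sites (bp)
    group: str = "other"

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError(f"line {self.sample}: T must be positive")
        if self.N <= 0:
            raise ValueError(f"line {self.sample}: N must be positive")


def index_metadata(metadata: Iterable[LineMetadata]) -> dict[str, LineMetadata]:
    idx: dict[str, LineMetadata] = {}
    for meta in metadata:
        if meta.sample in idx:
            raise ValueError(f"duplicate sample id {meta.sample!r} in metadata")
        idx[meta.sample] = meta
    return idx
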