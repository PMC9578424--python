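"""Readers and writers for the formats the pipeline touches.

FASTA and GFF3 come in through Biopython and gffutils; variant calls come in
as GATK-style VCF (via cyvcf2) or as the package's own breseq-like TSV
dialect, which is also the round-trip output format. All coordinates stay
1-based inclusive.
"""

from __future__ import annotations

import os
from dataclasses import fields as dataclass_fields
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO

from .core import (
    FormatError,
    GeneModel,
    LineMetadata,
    MutationRecord,
    ReferenceGenome,
)

#: stable column order of the mutation TSV dialect
MUTATION_COLUMNS = [
    "sample",
    "contig",
    "position",
    "ref",
    "alt",
    "mclass",
    "allele_frequency",
    "region",
    "effect",
    "spectrum_class",
    "genes",
    "ref_mismatch",
]

METADATA_COLUMNS = ["sample", "T", "N", "group"]


def read_fasta(path: str | os.PathLike) -> ReferenceGenome:
    """Load a FASTA file into a ReferenceGenome, uppercasing sequences."""
    contigs: dict[str, str] = {}
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in contigs:
                raise FormatError(f"duplicate contig id {rec.id!r} in {path}")
            contigs[rec.id] = str(rec.seq).upper()
    except (ValueError, AttributeError) as exc:  # Biopython parse failures
        raise FormatError(f"malformed FASTA {path}: {exc}") from exc
    if not contigs:
        raise FormatError(f"no FASTA records in {path}")
    return ReferenceGenome(contigs)


def write_fasta(genome: ReferenceGenome, path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_gff(
    path: str | os.PathLike,
    feature_types: Sequence[str] = ("CDS",),
) -> list[GeneModel]:
    """Load gene models from GFF3, keeping CDS features by default.

    Coordinates are kept exactly as in the file (1-based inclusive); the
    strand is preserved and minus-strand coordinates are never flipped.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for feat in db.all_features():
        if feat.featuretype not in feature_types:
            continue
        if feat.end < feat.start:
            raise FormatError(f"feature at {feat.seqid}:{feat.start} has end < start")
        attrs = feat.attributes
        gene_id = (attrs.get("ID") or attrs.get("gene_id") or [f"{feat.seqid}:{feat.start}-{feat.end}"])[0]
        name = (attrs.get("Name") or attrs.get("gene") or [""])[0]
        phase = 0 if feat.frame in (None, ".", "") else int(feat.frame)
        genes.append(
            GeneModel(
                gene_id=gene_id,
                name=name,
                contig=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand if feat.strand in "+-" else "+",
                is_cds=feat.featuretype == "CDS",
                phase=phase,
            )
        )
    return genes


def write_gff(genes: Iterable[GeneModel], path: str | os.PathLike) -> None:
    """Write gene models as GFF3 CDS/gene rows."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            ftype = "CDS" if g.is_cds else "gene"
            attrs = f"ID={g.gene_id}"
            if g.name:
                attrs += f";Name={g.name}"
            fh.write(
                f"{g.contig}\tmutaccum\t{ftype}\t{g.start}\t{g.end}\t.\t{g.strand}\t"
                f"{g.phase if g.is_cds else '.'}\t{attrs}\n"
            )


def _vcf_records(path: str, sample: Optional[str]) -> list[MutationRecord]:
    from cyvcf2 import VCF

    records: list[MutationRecord] = []
    vcf = VCF(str(path))
    default_sample = sample or (vcf.samples[0] if vcf.samples else os.path.basename(str(path)))
    for variant in vcf:
        afs = variant.INFO.get("AF")
        if afs is not None and not isinstance(afs, (tuple, list)):
            afs = (afs,)
        for i, alt in enumerate(variant.ALT):
            af = float(afs[i]) if afs is not None and i < len(afs) else None
            records.append(
                MutationRecord(
                    sample=default_sample,
                    contig=variant.CHROM,
                    position=variant.POS,
                    ref=variant.REF,
                    alt=alt,
                    allele_frequency=af,
                )
            )
    return records


def _tsv_records(path: str) -> list[MutationRecord]:
    frame = pd.read_csv(path, sep="\t", dtype={"sample": str, "contig": str})
    missing = {"sample", "contig", "position", "ref", "alt"} - set(frame.columns)
    if missing:
        raise FormatError(f"mutation TSV {path} lacks columns: {sorted(missing)}")
    records = []
    for row in frame.itertuples(index=False):
        d = row._asdict()
        af = d.get("allele_frequency")
        genes = d.get("genes")
        records.append(
            MutationRecord(
                sample=str(d["sample"]),
                contig=str(d["contig"]),
                position=int(d["position"]),
                ref=str(d["ref"]),
                alt=str(d["alt"]),
                mclass=_opt(d.get("mclass")) or "",
                allele_frequency=None if pd.isna(af) else float(af),
                region=_opt(d.get("region")),
                effect=_opt(d.get("effect")),
                spectrum_class=_opt(d.get("spectrum_class")),
                genes=tuple(str(genes).split(",")) if _opt(genes) else (),
                ref_mismatch=bool(d.get("ref_mismatch", False)),
            )
        )
    return records


def _opt(value) -> Optional[str]:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "" or str(value) == "nan":
        return None
    return str(value)


def read_mutations(
    path: str | os.PathLike,
    dialect: str = "tsv",
    sample: Optional[str] = None,
) -> list[MutationRecord]:
    """Read mutation calls from VCF or the package TSV dialect.

    Multi-allelic VCF rows are split into one record per alternate allele;
    the INFO AF field, when present, becomes the allele frequency.
    """
    if dialect == "vcf":
        return _vcf_records(str(path), sample)
    if dialect == "tsv":
        return _tsv_records(str(path))
    raise ValueError(f"unknown dialect {dialect!r}; expected 'vcf' or 'tsv'")


def mutations_to_frame(records: Iterable[MutationRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "sample": r.sample,
                "contig": r.contig,
                "position": r.position,
                "ref": r.ref,
                "alt": r.alt,
                "mclass": r.mclass,
                "allele_frequency": r.allele_frequency,
                "region": r.region,
                "effect": r.effect,
                "spectrum_class": r.spectrum_class,
                "genes": ",".join(r.genes),
                "ref_mismatch": r.ref_mismatch,
            }
        )
    return pd.DataFrame(rows, columns=MUTATION_COLUMNS)


def write_table(collection, path: str | os.PathLike) -> None:
    """Write a result collection as a TSV with a header and stable columns.

    Mutation-record lists round-trip through ``read_mutations(..., "tsv")``;
    DataFrames and lists of dataclasses are written with their own columns.
    """
    frame = as_frame(collection)
    frame.to_csv(path, sep="\t", index=False)


def as_frame(collection) -> pd.DataFrame:
    if isinstance(collection, pd.DataFrame):
        return collection
    items = list(collection)
    if items and isinstance(items[0], MutationRecord):
        return mutations_to_frame(items)
    if items and isinstance(items[0], LineMetadata):
        return pd.DataFrame(
            [{"sample": m.sample, "T": m.T, "N": m.N, "group": m.group} for m in items],
            columns=METADATA_COLUMNS,
        )
    if items and hasattr(items[0], "__dataclass_fields__"):
        cols = [f.name for f in dataclass_fields(items[0])]
        return pd.DataFrame([{c: getattr(it, c) for c in cols} for it in items], columns=cols)
    if not items:
        return mutations_to_frame([])  # header-only mutation table
    return pd.DataFrame(items)


def read_metadata(path: str | os.PathLike) -> list[LineMetadata]:
    frame = pd.read_csv(path, sep="\t")
    missing = set(METADATA_COLUMNS) - set(frame.columns)
    if missing:
        raise FormatError(f"metadata TSV {path} lacks columns: {sorted(missing)}")
    return [
        LineMetadata(sample=str(r.sample), T=float(r.T), N=float(r.N), group=str(r.group))
        for r in frame.itertuples(index=False)
    ]
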