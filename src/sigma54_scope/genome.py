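"""Annotated-genome data model, I/O and coding-sequence arithmetic.

Coordinates are 0-based half-open everywhere inside the package; every file
boundary (FASTA/GFF3/GenBank, reports, variant tables) speaks 1-based
inclusive, the convention of GFF3 and of published mutation tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

from Bio import SeqIO
from Bio.Data import IUPACData
from Bio.Seq import Seq

__all__ = [
    "Feature",
    "CodonPosition",
    "AnnotatedGenome",
    "load_genome",
    "write_genome",
    "extract_cds",
    "translate_cds",
    "locate_in_cds",
    "codon_from_cds_position",
    "reverse_complement",
]

_IUPAC_CODES = set(IUPACData.ambiguous_dna_letters.upper())

STOP_SENTINEL = "X"  # premature/terminal stop rendered as in mutation tables ("Q -> X")


@dataclass
class Feature:
    """A gene or CDS interval on one contig.

    ``start``/``end`` are 0-based half-open genomic coordinates; ``strand``
    is ``"+"`` or ``"-"``; ``feature_id`` is the locus tag.
    """

    feature_id: str
    contig_id: str
    start: int
    end: int
    strand: Literal["+", "-"]
    kind: Literal["gene", "CDS"] = "CDS"
    product: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"feature {self.feature_id}: start must be < end "
                f"(got [{self.start}, {self.end}))"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"feature {self.feature_id}: bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CodonPosition:
    """Location of a nucleotide within a coding sequence.

    ``cds_position`` is the 1-based offset from the CDS 5' end on the coding
    strand; ``codon_index`` the 1-based residue number; ``offset_in_codon``
    in {1, 2, 3}.
    """

    cds_position: int
    codon_index: int
    offset_in_codon: int

    def __post_init__(self) -> None:
        expected = (self.cds_position - 1) // 3 + 1
        if self.codon_index != expected:
            raise ValueError(
                f"inconsistent codon arithmetic: cds_position {self.cds_position} "
                f"implies codon {expected}, got {self.codon_index}"
            )
        if 3 * (self.codon_index - 1) + self.offset_in_codon != self.cds_position:
            raise ValueError("offset_in_codon inconsistent with cds_position")


@dataclass
class AnnotatedGenome:
    """One or more contig sequences plus strand-aware gene/CDS features."""

    contigs: dict[str, str]
    features: list[Feature] = field(default_factory=list)
    source_label: str = ""

    def __post_init__(self) -> None:
        self.contigs = {cid: seq.upper() for cid, seq in self.contigs.items()}
        self.validate()

    def validate(self) -> None:
        for cid, seq in self.contigs.items():
            bad = set(seq) - _IUPAC_CODES
            if bad:
                raise ValueError(f"contig {cid}: non-IUPAC characters {sorted(bad)}")
        for feat in self.features:
            if feat.contig_id not in self.contigs:
                raise ValueError(
                    f"feature {feat.feature_id}: unknown contig {feat.contig_id}"
                )
            if feat.end > len(self.contigs[feat.contig_id]):
                raise ValueError(
                    f"feature {feat.feature_id}: interval [{feat.start}, {feat.end}) "
                    f"outside contig {feat.contig_id} "
                    f"(length {len(self.contigs[feat.contig_id])})"
                )

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def feature(self, feature_id: str) -> Feature:
        for feat in self.features:
            if feat.feature_id == feature_id:
                return feat
        raise KeyError(f"unknown feature id {feature_id!r}")

    def cds_features(self, contig_id: str | None = None) -> list[Feature]:
        return [
            f
            for f in self.features
            if f.kind == "CDS" and (contig_id is None or f.contig_id == contig_id)
        ]


def reverse_complement(seq: str) -> str:
    """Reverse complement preserving IUPAC degeneracy codes."""
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# I/O


def _parse_gff3(annotation_path: str | Path, contigs: dict[str, str]) -> tuple[list[Feature], list[str]]:
    import gffutils

    db = gffutils.create_db(
        str(annotation_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    features: list[Feature] = []
    skipped: list[str] = []
    for rec in db.all_features():
        if rec.featuretype not in ("gene", "CDS"):
            skipped.append(f"{rec.featuretype} at {rec.seqid}:{rec.start}-{rec.end}")
            continue
        fid = rec.attributes.get("ID", rec.attributes.get("locus_tag", [rec.id]))[0]
        product = rec.attributes.get("product", [""])[0]
        if rec.seqid not in contigs:
            raise ValueError(
                f"annotation contig {rec.seqid!r} (feature {fid}) has no FASTA record"
            )
        feat = Feature(
            feature_id=fid,
            contig_id=rec.seqid,
            start=rec.start - 1,  # GFF3 1-based inclusive -> half-open
            end=rec.end,
            strand="-" if rec.strand == "-" else "+",
            kind=rec.featuretype,  # type: ignore[arg-type]
            product=product,
        )
        if feat.end > len(contigs[rec.seqid]):
            raise ValueError(
                f"CDS {fid} extends beyond contig {rec.seqid} "
                f"(end {feat.end} > {len(contigs[rec.seqid])})"
            )
        features.append(feat)
    return features, skipped


def _parse_genbank(path: str | Path) -> tuple[dict[str, str], list[Feature], list[str]]:
    contigs: dict[str, str] = {}
    features: list[Feature] = []
    skipped: list[str] = []
    for record in SeqIO.parse(str(path), "genbank"):
        contigs[record.id] = str(record.seq).upper()
        for sf in record.features:
            if sf.type not in ("gene", "CDS"):
                skipped.append(f"{sf.type} at {record.id}:{sf.location}")
                continue
            tags = sf.qualifiers.get("locus_tag") or sf.qualifiers.get("gene")
            if not tags:
                skipped.append(f"{sf.type} without locus_tag at {record.id}:{sf.location}")
                continue
            features.append(
                Feature(
                    feature_id=tags[0],
                    contig_id=record.id,
                    start=int(sf.location.start),
                    end=int(sf.location.end),
                    strand="-" if sf.location.strand == -1 else "+",
                    kind=sf.type,  # type: ignore[arg-type]
                    product=sf.qualifiers.get("product", [""])[0],
                )
            )
    return contigs, features, skipped


def load_genome(
    fasta_path: str | Path | None,
    annotation_path: str | Path,
    dialect: Literal["gff3", "genbank"] = "gff3",
    source_label: str = "",
) -> AnnotatedGenome:
    """Read a genome from FASTA + GFF3 or from a GenBank flat file.

    GenBank files carry their own sequence, so ``fasta_path`` may be None for
    ``dialect="genbank"``. Records other than gene/CDS are skipped and listed
    in a warning. Unresolvable contig ids and out-of-bounds CDS are hard
    errors naming the offending feature.
    """
    if dialect == "genbank":
        contigs, features, skipped = _parse_genbank(annotation_path)
    elif dialect == "gff3":
        if fasta_path is None:
            raise ValueError("GFF3 dialect requires a FASTA file")
        contigs = {
            rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")
        }
        if not contigs:
            raise ValueError(f"no FASTA records in {fasta_path}")
        features, skipped = _parse_gff3(annotation_path, contigs)
    else:
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    if skipped:
        warnings.warn(f"skipped {len(skipped)} non-gene/CDS records: {skipped[:5]}")
    return AnnotatedGenome(contigs=contigs, features=features, source_label=source_label)


def write_genome(
    genome: AnnotatedGenome, fasta_path: str | Path, gff3_path: str | Path
) -> None:
    """Write FASTA plus GFF3 (1-based inclusive) for an annotated genome."""
    with open(fasta_path, "w") as fh:
        for cid, seq in genome.contigs.items():
            fh.write(f">{cid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for cid, seq in genome.contigs.items():
            fh.write(f"##sequence-region {cid} 1 {len(seq)}\n")
        for feat in genome.features:
            attrs = f"ID={feat.feature_id};locus_tag={feat.feature_id}"
            if feat.product:
                attrs += f";product={feat.product}"
            fh.write(
                "\t".join(
                    [
                        feat.contig_id,
                        "sigma54_scope",
                        feat.kind,
                        str(feat.start + 1),
                        str(feat.end),
                        ".",
                        feat.strand,
                        "0" if feat.kind == "CDS" else ".",
                        attrs,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Sequence arithmetic


def extract_cds(genome: AnnotatedGenome, feature_id: str) -> str:
    """Coding-strand nucleotide sequence of a CDS feature.

    Minus-strand features are reverse-complemented so the returned string
    always starts at the CDS 5' end.
    """
    feat = genome.feature(feature_id)
    if feat.kind != "CDS":
        raise ValueError(f"feature {feature_id} is {feat.kind}, not CDS")
    seq = genome.contigs[feat.contig_id][feat.start : feat.end]
    return reverse_complement(seq) if feat.strand == "-" else seq


def translate_cds(sequence: str, table: int = 11) -> str:
    """Translate a CDS with the bacterial code; stops render as ``X``.

    The ``X`` sentinel follows the notation of nonsense rows in mutation
    tables ("Q -> X"). Internal stops are permitted (the caller decides
    whether they signify truncation); length must be a multiple of 3.
    """
    sequence = sequence.upper()
    remainder = len(sequence) % 3
    if remainder:
        raise ValueError(
            f"CDS length {len(sequence)} not divisible by 3 (remainder {remainder})"
        )
    aa = str(Seq(sequence).translate(table=table))
    return aa.replace("*", STOP_SENTINEL)


def codon_from_cds_position(cds_position: int) -> CodonPosition:
    """Map a 1-based CDS nucleotide offset to (codon index, offset in codon)."""
    if cds_position < 1:
        raise ValueError(f"cds_position must be >= 1, got {cds_position}")
    codon_index = (cds_position - 1) // 3 + 1
    offset = cds_position - 3 * (codon_index - 1)
    return CodonPosition(cds_position, codon_index, offset)


def locate_in_cds(feature: Feature, genome_position: int) -> CodonPosition | None:
    """Place a 1-based genomic position within a CDS, or None if outside.

    For minus-strand features the CDS position counts from the 5' end on the
    coding strand, i.e. from the rightmost genomic base of the feature.
    """
    pos0 = genome_position - 1
    if pos0 < feature.start or pos0 >= feature.end:
        return None
    if feature.strand == "+":
        cds_position = pos0 - feature.start + 1
    else:
        cds_position = feature.end - pos0
    return codon_from_cds_position(cds_position)
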