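"""Point-mutation effect annotation in the style of resequencing mutation tables.

Given an annotated genome and a list of single-nucleotide substitutions, each
variant is classified as Substitution (missense), Truncation (nonsense, stop
rendered ``X``), None (synonymous) or Intergenic, with the CDS position and
amino-acid change computed from codon arithmetic. Minus-strand genes have
their alleles complemented onto the coding strand before codon substitution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .genome import (
    AnnotatedGenome,
    Feature,
    STOP_SENTINEL,
    extract_cds,
    locate_in_cds,
    translate_cds,
)

__all__ = [
    "Variant",
    "VariantEffect",
    "EFFECT_SUBSTITUTION",
    "EFFECT_TRUNCATION",
    "EFFECT_NONE",
    "EFFECT_INTERGENIC",
    "annotate_variant",
    "annotate_table",
    "read_variants_vcf",
    "read_variants_tsv",
    "write_effect_table",
]

EFFECT_SUBSTITUTION = "Substitution"
EFFECT_TRUNCATION = "Truncation"
EFFECT_NONE = "None"
EFFECT_INTERGENIC = "Intergenic"
EFFECT_AMBIGUOUS = "Ambiguous"

_BASES = {"A", "C", "G", "T"}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class Variant:
    """A single-nucleotide substitution, 1-based genomic position."""

    contig_id: str
    genome_position: int
    ref_base: str
    alt_base: str

    def __post_init__(self) -> None:
        ref, alt = self.ref_base.upper(), self.alt_base.upper()
        if len(ref) != 1 or len(alt) != 1:
            raise ValueError(
                f"only single-nucleotide substitutions are supported, got "
                f"{ref!r} -> {alt!r} at {self.contig_id}:{self.genome_position}"
            )
        if ref not in _BASES or alt not in _BASES:
            raise ValueError(f"bases must be A/C/G/T, got {ref!r} -> {alt!r}")
        if ref == alt:
            raise ValueError(f"ref == alt ({ref}) at {self.genome_position}")
        object.__setattr__(self, "ref_base", ref)
        object.__setattr__(self, "alt_base", alt)


@dataclass(frozen=True)
class VariantEffect:
    """Classified consequence of one variant against one (or no) CDS."""

    variant: Variant
    gene_id: str | None  # None => intergenic
    description: str = ""
    cds_position: int | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None
    effect: str = EFFECT_INTERGENIC
    stop_loss: bool = False

    @property
    def amino_acid_change(self) -> str:
        if self.gene_id is None:
            return "N/A"
        if self.effect == EFFECT_NONE:
            return "none"
        return f"{self.ref_aa} -> {self.alt_aa}"


def _overlapping_cds(genome: AnnotatedGenome, variant: Variant) -> list[Feature]:
    pos0 = variant.genome_position - 1
    return [
        f
        for f in genome.cds_features(variant.contig_id)
        if f.start <= pos0 < f.end
    ]


def annotate_variant(
    genome: AnnotatedGenome, variant: Variant
) -> list[VariantEffect]:
    """Classify one substitution against every CDS containing it.

    Returns one effect per overlapping CDS, or a single Intergenic effect.
    The observed genome base must equal ``ref_base`` (a mismatch signals an
    assembly/coordinate mix-up and is a hard error carrying the observed
    base).
    """
    if variant.contig_id not in genome.contigs:
        raise ValueError(f"unknown contig {variant.contig_id!r}")
    seq = genome.contigs[variant.contig_id]
    pos0 = variant.genome_position - 1
    if not 0 <= pos0 < len(seq):
        raise ValueError(
            f"position {variant.genome_position} outside contig "
            f"{variant.contig_id} (length {len(seq)})"
        )
    observed = seq[pos0]
    if observed != variant.ref_base:
        raise ValueError(
            f"ref-base mismatch at {variant.contig_id}:{variant.genome_position}: "
            f"expected {variant.ref_base}, genome has {observed}"
        )
    features = _overlapping_cds(genome, variant)
    if not features:
        return [VariantEffect(variant=variant, gene_id=None)]
    effects = []
    for feat in features:
        effects.append(_annotate_in_cds(genome, variant, feat))
    return effects


def _annotate_in_cds(
    genome: AnnotatedGenome, variant: Variant, feat: Feature
) -> VariantEffect:
    pos = locate_in_cds(feat, variant.genome_position)
    assert pos is not None
    cds = extract_cds(genome, feat.feature_id)
    if len(cds) % 3:
        raise ValueError(
            f"CDS {feat.feature_id} length {len(cds)} not divisible by 3; "
            "cannot classify codon effect"
        )
    ref, alt = variant.ref_base, variant.alt_base
    if feat.strand == "-":
        ref = ref.translate(_COMPLEMENT)
        alt = alt.translate(_COMPLEMENT)
    i = pos.cds_position - 1
    if cds[i] != ref:
        raise ValueError(
            f"coding-strand base at CDS position {pos.cds_position} of "
            f"{feat.feature_id} is {cds[i]}, expected {ref}"
        )
    codon_start = 3 * (pos.codon_index - 1)
    ref_codon = cds[codon_start : codon_start + 3]
    alt_codon = (
        ref_codon[: pos.offset_in_codon - 1] + alt + ref_codon[pos.offset_in_codon :]
    )
    if set(ref_codon) - _BASES:
        return VariantEffect(
            variant=variant,
            gene_id=feat.feature_id,
            description=feat.product,
            cds_position=pos.cds_position,
            effect=EFFECT_AMBIGUOUS,
        )
    ref_aa = translate_cds(ref_codon)
    alt_aa = translate_cds(alt_codon)
    stop_loss = False
    if ref_aa == alt_aa:
        effect = EFFECT_NONE
    elif alt_aa == STOP_SENTINEL and ref_aa != STOP_SENTINEL:
        effect = EFFECT_TRUNCATION
    else:
        effect = EFFECT_SUBSTITUTION
        stop_loss = ref_aa == STOP_SENTINEL
    return VariantEffect(
        variant=variant,
        gene_id=feat.feature_id,
        description=feat.product,
        cds_position=pos.cds_position,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        effect=effect,
        stop_loss=stop_loss,
    )


TABLE_COLUMNS = [
    "locus_tag",
    "description",
    "change",
    "genome_position",
    "cds_position",
    "amino_acid_change",
    "protein_effect",
]


def annotate_table(
    genome: AnnotatedGenome, variants: Sequence[Variant]
) -> pd.DataFrame:
    """Annotate a variant list into a mutation-table DataFrame.

    One row per (variant, overlapping CDS) in the column order of published
    resequencing tables; duplicate variants are dropped with a warning;
    per-variant errors are aggregated and reported, annotation continues.
    """
    seen: set[Variant] = set()
    unique: list[Variant] = []
    for v in variants:
        if v in seen:
            warnings.warn(f"duplicate variant at {v.contig_id}:{v.genome_position} dropped")
            continue
        seen.add(v)
        unique.append(v)
    unique.sort(key=lambda v: (v.contig_id, v.genome_position))
    rows = []
    errors = []
    for v in unique:
        try:
            effects = annotate_variant(genome, v)
        except ValueError as exc:
            errors.append(str(exc))
            continue
        for e in effects:
            rows.append(
                {
                    "locus_tag": e.gene_id or "N/A",
                    "description": e.description if e.gene_id else "Intergenic",
                    "change": f"{v.ref_base} -> {v.alt_base}",
                    "genome_position": v.genome_position,
                    "cds_position": e.cds_position if e.cds_position else "N/A",
                    "amino_acid_change": e.amino_acid_change,
                    "protein_effect": e.effect,
                }
            )
    if errors:
        warnings.warn(f"{len(errors)} variants failed annotation: {errors[:3]}")
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def read_variants_vcf(path: str | Path) -> list[Variant]:
    """Minimal VCF reader: SNVs only, first ALT allele of multi-allelic records."""
    import pysam

    variants = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            alts = rec.alts or ()
            if len(alts) > 1:
                warnings.warn(
                    f"multi-allelic record at {rec.chrom}:{rec.pos}; keeping first ALT"
                )
            if not alts:
                continue
            ref, alt = rec.ref, alts[0]
            if len(ref) != 1 or len(alt) != 1:
                warnings.warn(
                    f"non-SNV record at {rec.chrom}:{rec.pos} ({ref}->{alt}) skipped; "
                    "only single-nucleotide substitutions are supported"
                )
                continue
            variants.append(Variant(rec.chrom, rec.pos, ref, alt))
    return variants


def read_variants_tsv(path: str | Path) -> list[Variant]:
    """TSV reader with columns contig, genome_position, ref, alt."""
    df = pd.read_csv(path, sep="\t")
    return [
        Variant(str(r.contig), int(r.genome_position), str(r.ref), str(r.alt))
        for r in df.itertuples()
    ]


def write_effect_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)
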