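"""Seeded synthetic-genome, variant and Cq-table generators with ground truth.

The generator emulates, at desk scale, the kind of annotated clostridial
chromosome the scanning pipeline consumes: protein-coding genes on both
strands, a subset of transcriptional units carrying a planted -24/-12
consensus instance (degenerate N/W positions randomized) at a recorded
upstream distance, enhancer-binding-protein genes planted next to designated
units, point mutations of every effect class, and noisy Cq tables inverted
from known true expression ratios. Every output is reproducible from
(config, seed) and every planted fact is recorded in a truth table, so
downstream stages can be tested against known answers without downloads.

Background sequence is i.i.d. (uniform by default; a low-GC Clostridium-like
mode is available) and, when ``motif_free_background`` is set, spontaneous
consensus matches are removed by rejection-resampling the offending window,
so the only hits a scanner can find are the planted ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import AnnotatedGenome, Feature, reverse_complement, translate_cds
from .motifs import SIGMA54_CONSENSUS, ConsensusPattern, scan_consensus
from .qpcr import CqTable
from .variants import (
    EFFECT_INTERGENIC,
    EFFECT_NONE,
    EFFECT_SUBSTITUTION,
    EFFECT_TRUNCATION,
    Variant,
)

__all__ = [
    "GenomeSimConfig",
    "PlantedUnit",
    "TruthTable",
    "generate_genome",
    "generate_variants",
    "generate_cq_table",
    "generate_genome_family",
    "EBP_PRODUCT",
]

_BASES = np.array(list("ACGT"))
_STOPS = ("TAA", "TAG", "TGA")

EBP_PRODUCT = "sigma-54 dependent transcriptional regulator (AAA+ EBP)"


@dataclass(frozen=True)
class GenomeSimConfig:
    """Study conditions for one synthetic genome.

    Defaults emulate a scaled-down clostridial chromosome: dozens of genes on
    a 100 kb contig, a handful of sigma-54 units with consensus sites planted
    0..window bp upstream, EBP genes beside about half of them.
    """

    n_contigs: int = 1
    contig_length: int = 100_000
    n_genes: int = 30
    gene_codon_range: tuple[int, int] = (150, 350)
    strand_prob: float = 0.5
    n_regulon_units: int = 5
    operon_extra_range: tuple[int, int] = (0, 2)
    window: int = 500
    n_ebp_units: int | None = None  # default: half the units
    ebp_span: int = 1500
    gc_content: float = 0.5
    motif_free_background: bool = True
    pattern: str = SIGMA54_CONSENSUS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regulon_units > self.n_genes:
            raise ValueError("more regulon units than genes")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must be in (0, 1)")


@dataclass
class PlantedUnit:
    """Ground truth for one planted promoter/transcriptional unit."""

    contig_id: str
    motif_start: int  # 0-based half-open genomic interval of the 16-mer
    motif_end: int
    strand: Literal["+", "-"]
    distance: int
    lead_gene: str
    unit_genes: list[str]
    ebp: bool
    ebp_gene: str | None


@dataclass
class TruthTable:
    """Everything the generator planted, keyed for downstream verification."""

    units: list[PlantedUnit] = field(default_factory=list)
    cds_sequences: dict[str, str] = field(default_factory=dict)
    variant_classes: list[tuple[Variant, str]] = field(default_factory=list)
    true_ratios: dict[tuple[str, str], float] = field(default_factory=dict)
    efficiencies: dict[str, float] = field(default_factory=dict)
    conservation: dict[str, dict[str, str]] = field(default_factory=dict)

    def units_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "contig": [u.contig_id for u in self.units],
                "motif_start": [u.motif_start + 1 for u in self.units],
                "motif_end": [u.motif_end for u in self.units],
                "strand": [u.strand for u in self.units],
                "distance": [u.distance for u in self.units],
                "lead_gene": [u.lead_gene for u in self.units],
                "unit": ["-".join(u.unit_genes) for u in self.units],
                "ebp": [u.ebp for u in self.units],
                "ebp_gene": [u.ebp_gene or "" for u in self.units],
            }
        )


# ---------------------------------------------------------------------------
# Low-level helpers


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=n, p=p)]) if n else ""


def _random_cds(rng: np.random.Generator, n_codons: int, gc: float) -> str:
    """ATG + (n_codons - 1) random sense codons + one stop codon."""
    body = _random_seq(rng, 3 * (n_codons - 1), gc)
    codons = [body[i : i + 3] for i in range(0, len(body), 3)]
    for i, c in enumerate(codons):
        while c in _STOPS:
            c = _random_seq(rng, 3, gc)
        codons[i] = c
    stop = _STOPS[rng.integers(0, 3)]
    return "ATG" + "".join(codons) + stop


def _motif_instance(rng: np.random.Generator, pattern: ConsensusPattern) -> str:
    out = []
    for ch, allowed in zip(pattern.pattern, pattern.allowed):
        if len(allowed) == 1:
            out.append(ch)
        else:
            choices = sorted(allowed)
            out.append(choices[rng.integers(0, len(choices))])
    return "".join(out)


# ---------------------------------------------------------------------------
# Block layout


@dataclass
class _GeneSpec:
    gene_id: str
    cds: str  # coding-strand sequence
    product: str = "hypothetical protein"


@dataclass
class _BlockSpec:
    """One layout unit in coding orientation: [motif, gap d,] genes, [EBP]."""

    genes: list[_GeneSpec]
    strand: Literal["+", "-"]
    motif_seq: str | None = None
    distance: int = 0
    intra_gaps: list[int] = field(default_factory=list)
    ebp: _GeneSpec | None = None
    ebp_gap: int = 0


def _build_contigs(
    blocks: Sequence[_BlockSpec], config: GenomeSimConfig, rng: np.random.Generator
) -> tuple[dict[str, str], list[Feature], list[PlantedUnit], dict[str, str]]:
    contig_ids = [f"contig_{i + 1}" for i in range(config.n_contigs)]
    margin = 300
    gap_lo = config.ebp_span + 100
    gap_hi = config.ebp_span + 500
    contig_seqs = {cid: "" for cid in contig_ids}
    features: list[Feature] = []
    units: list[PlantedUnit] = []
    cds_truth: dict[str, str] = {}
    ci = 0
    cursor = margin + int(rng.integers(0, 200))
    lead_in = cursor
    parts: dict[str, list[str]] = {cid: [] for cid in contig_ids}
    part_cursor = {cid: 0 for cid in contig_ids}

    def _emit(cid: str, at: int, seq: str) -> None:
        # append background up to `at`, then seq
        gap = at - part_cursor[cid]
        assert gap >= 0
        parts[cid].append(_random_seq(rng, gap, config.gc_content))
        parts[cid].append(seq)
        part_cursor[cid] = at + len(seq)

    for block in blocks:
        # assemble block in coding orientation, tracking local elements
        local: list[str] = []
        pos = 0
        motif_local: tuple[int, int] | None = None
        gene_locals: list[tuple[int, int, _GeneSpec]] = []
        if block.motif_seq is not None:
            motif_local = (0, len(block.motif_seq))
            local.append(block.motif_seq)
            pos = len(block.motif_seq)
            local.append(_random_seq(rng, block.distance, config.gc_content))
            pos += block.distance
        for gi, gene in enumerate(block.genes):
            if gi > 0:
                g = block.intra_gaps[gi - 1]
                local.append(_random_seq(rng, g, config.gc_content))
                pos += g
            gene_locals.append((pos, pos + len(gene.cds), gene))
            local.append(gene.cds)
            pos += len(gene.cds)
        ebp_local: tuple[int, int] | None = None
        if block.ebp is not None:
            local.append(_random_seq(rng, block.ebp_gap, config.gc_content))
            pos += block.ebp_gap
            ebp_local = (pos, pos + len(block.ebp.cds))
            local.append(block.ebp.cds)
            pos += len(block.ebp.cds)
        block_seq = "".join(local)
        blen = len(block_seq)
        if block.strand == "-":
            block_seq = reverse_complement(block_seq)

        # find room
        if cursor + blen + margin > config.contig_length:
            ci += 1
            if ci >= config.n_contigs:
                raise ValueError(
                    "infeasible packing: blocks do not fit the configured contigs"
                )
            cursor = margin + int(rng.integers(0, 200))
        cid = contig_ids[ci]
        _emit(cid, cursor, block_seq)

        def to_genomic(local_iv: tuple[int, int]) -> tuple[int, int]:
            a, b = local_iv
            if block.strand == "+":
                return cursor + a, cursor + b
            return cursor + blen - b, cursor + blen - a

        for a, b, gene in gene_locals:
            gs, ge = to_genomic((a, b))
            features.append(
                Feature(gene.gene_id, cid, gs, ge, block.strand, "CDS", gene.product)
            )
            cds_truth[gene.gene_id] = gene.cds
        ebp_id = None
        if block.ebp is not None and ebp_local is not None:
            gs, ge = to_genomic(ebp_local)
            features.append(
                Feature(block.ebp.gene_id, cid, gs, ge, block.strand, "CDS", block.ebp.product)
            )
            cds_truth[block.ebp.gene_id] = block.ebp.cds
            ebp_id = block.ebp.gene_id
        if block.motif_seq is not None and motif_local is not None:
            ms, me = to_genomic(motif_local)
            units.append(
                PlantedUnit(
                    contig_id=cid,
                    motif_start=ms,
                    motif_end=me,
                    strand=block.strand,
                    distance=block.distance,
                    lead_gene=block.genes[0].gene_id,
                    unit_genes=[g.gene_id for g in block.genes],
                    ebp=block.ebp is not None,
                    ebp_gene=ebp_id,
                )
            )
        cursor += blen + int(rng.integers(gap_lo, gap_hi + 1))

    # pad every contig to its configured length
    for cid in contig_ids:
        tail = config.contig_length - part_cursor[cid]
        parts[cid].append(_random_seq(rng, tail, config.gc_content))
        contig_seqs[cid] = "".join(parts[cid])
        assert len(contig_seqs[cid]) == config.contig_length
    return contig_seqs, features, units, cds_truth


def _scrub_background(
    contigs: dict[str, str],
    features: list[Feature],
    units: list[PlantedUnit],
    pattern: ConsensusPattern,
    rng: np.random.Generator,
    gc: float,
    max_rounds: int = 1000,
) -> dict[str, str]:
    """Rejection-resample spontaneous consensus matches out of the genome.

    Planted sites are preserved; a spurious hit overlapping a gene triggers a
    redraw of that gene's sense codons, a hit in plain background redraws the
    window, and a hit overlapping a planted motif re-randomizes the planted
    site's degenerate positions (it still matches the consensus afterwards).
    """
    planted = {(u.contig_id, u.motif_start, u.strand) for u in units}
    planted_iv = [(u.contig_id, u.motif_start, u.motif_end) for u in units]
    work = {cid: bytearray(seq.encode()) for cid, seq in contigs.items()}

    def redraw_gene_codons(f: Feature, lo: int, hi: int) -> bool:
        """Redraw the sense codons of f covering genomic [lo, hi).

        Start and stop codons are preserved; the protein changes by at most a
        handful of residues, so ortholog identity across derived genomes
        survives the scrub.
        """
        lo, hi = max(lo, f.start), min(hi, f.end)
        seq = work[f.contig_id][f.start : f.end].decode()
        cds = reverse_complement(seq) if f.strand == "-" else seq
        if f.strand == "+":
            c_lo, c_hi = lo - f.start, hi - f.start
        else:
            c_lo, c_hi = f.end - hi, f.end - lo
        n_codons = len(cds) // 3
        first = max(1, c_lo // 3)  # keep the start codon
        last = min(n_codons - 2, (c_hi - 1) // 3)  # keep the stop codon
        if first > last:
            return False
        codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        for i in range(first, last + 1):
            c = _random_seq(rng, 3, gc)
            while c in _STOPS:
                c = _random_seq(rng, 3, gc)
            codons[i] = c
        new_cds = "".join(codons)
        new_seq = reverse_complement(new_cds) if f.strand == "-" else new_cds
        work[f.contig_id][f.start : f.end] = new_seq.encode()
        return True

    for _ in range(max_rounds):
        genome = AnnotatedGenome(
            contigs={cid: b.decode() for cid, b in work.items()},
            features=[],
        )
        spurious = [
            h
            for h in scan_consensus(genome, pattern)
            if (h.contig_id, h.start, h.strand) not in planted
        ]
        if not spurious:
            return genome.contigs
        for h in spurious:
            over_motif = next(
                (
                    (c, s, e)
                    for c, s, e in planted_iv
                    if c == h.contig_id and s < h.end and h.start < e
                ),
                None,
            )
            if over_motif is not None:
                c, s, e = over_motif
                unit = next(u for u in units if (u.contig_id, u.motif_start) == (c, s))
                inst = _motif_instance(rng, pattern)
                if unit.strand == "-":
                    inst = reverse_complement(inst)
                work[c][s:e] = inst.encode()
                continue
            over_genes = [
                f
                for f in features
                if f.contig_id == h.contig_id and f.start < h.end and h.start < f.end
            ]
            changed = any(redraw_gene_codons(f, h.start, h.end) for f in over_genes)
            # redraw whatever part of the window is plain background
            covered = [(f.start, f.end) for f in over_genes] + [
                (s, e) for c, s, e in planted_iv if c == h.contig_id
            ]
            for p in range(h.start, h.end):
                if not any(s <= p < e for s, e in covered):
                    work[h.contig_id][p : p + 1] = _random_seq(rng, 1, gc).encode()
                    changed = True
            if not changed:
                # window buried in protected bases; nudge an overlapped gene's
                # interior codon nearest the window instead
                f = over_genes[0]
                mid = (h.start + h.end) // 2
                redraw_gene_codons(f, mid - 3, mid + 3)
    raise RuntimeError("could not scrub spontaneous motif matches within retry cap")


def _make_block_specs(
    config: GenomeSimConfig, rng: np.random.Generator, label: str
) -> list[_BlockSpec]:
    pattern = ConsensusPattern(config.pattern)
    n_ebp = (
        config.n_regulon_units // 2 if config.n_ebp_units is None else config.n_ebp_units
    )
    if n_ebp > config.n_regulon_units:
        raise ValueError("n_ebp_units exceeds n_regulon_units")
    lo, hi = config.gene_codon_range
    gene_no = 0

    def new_gene(product: str = "hypothetical protein") -> _GeneSpec:
        nonlocal gene_no
        gene_no += 1
        n_codons = int(rng.integers(lo, hi + 1))
        return _GeneSpec(f"{label}_g{gene_no:04d}", _random_cds(rng, n_codons, config.gc_content), product)

    blocks: list[_BlockSpec] = []
    n_filler = config.n_genes - config.n_regulon_units
    ebp_flags = [i < n_ebp for i in range(config.n_regulon_units)]
    for i in range(config.n_regulon_units):
        extra = int(
            rng.integers(config.operon_extra_range[0], config.operon_extra_range[1] + 1)
        )
        genes = [new_gene("sigma-54 regulated candidate")]
        genes += [new_gene("operon member") for _ in range(extra)]
        strand = "+" if rng.random() < config.strand_prob else "-"
        ebp = None
        ebp_gap = 0
        if ebp_flags[i]:
            nonlocal_id = gene_no + 1
            ebp = _GeneSpec(
                f"{label}_ebp{nonlocal_id:04d}",
                _random_cds(rng, int(rng.integers(lo, hi + 1)), config.gc_content),
                EBP_PRODUCT,
            )
            gene_no += 1
            ebp_gap = int(rng.integers(150, 401))
        blocks.append(
            _BlockSpec(
                genes=genes,
                strand=strand,
                motif_seq=_motif_instance(rng, pattern),
                distance=int(rng.integers(0, config.window + 1)),
                intra_gaps=[int(rng.integers(5, 41)) for _ in range(extra)],
                ebp=ebp,
                ebp_gap=ebp_gap,
            )
        )
    for _ in range(n_filler):
        strand = "+" if rng.random() < config.strand_prob else "-"
        blocks.append(_BlockSpec(genes=[new_gene()], strand=strand))
    # interleave unit and filler blocks deterministically
    order = rng.permutation(len(blocks))
    return [blocks[i] for i in order]


def generate_genome(
    config: GenomeSimConfig, label: str = "sim"
) -> tuple[AnnotatedGenome, TruthTable]:
    """Generate one annotated genome with planted sigma-54 promoter units.

    Returns the genome and a truth table recording every planted motif locus
    (with strand, upstream distance and target unit), every gene's coding
    sequence and every EBP placement. Deterministic for a fixed
    (config, label).
    """
    rng = np.random.default_rng(config.seed)
    pattern = ConsensusPattern(config.pattern)
    blocks = _make_block_specs(config, rng, label)
    contigs, features, units, cds_truth = _build_contigs(blocks, config, rng)
    if config.motif_free_background:
        contigs = _scrub_background(
            contigs, features, units, pattern, rng, config.gc_content
        )
    genome = AnnotatedGenome(
        contigs=contigs, features=features, source_label=label
    )
    # scrubbing may have redrawn a few gene codons: record the final sequences
    truth = TruthTable(units=units, cds_sequences=_extract_all_cds(genome))
    return genome, truth


def _extract_all_cds(genome: AnnotatedGenome) -> dict[str, str]:
    out = {}
    for f in genome.cds_features():
        seq = genome.contigs[f.contig_id][f.start : f.end]
        out[f.feature_id] = reverse_complement(seq) if f.strand == "-" else seq
    return out


# ---------------------------------------------------------------------------
# Variants


def _coding_to_genomic(feat: Feature, cds_position: int) -> int:
    """1-based genome position of a 1-based CDS offset."""
    if feat.strand == "+":
        return feat.start + cds_position
    return feat.end - cds_position + 1


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _plant_in_cds(
    rng: np.random.Generator,
    genome: AnnotatedGenome,
    feat: Feature,
    cds: str,
    effect: str,
) -> Variant | None:
    """Try once to realize an effect class by a single coding-strand edit."""
    n_codons = len(cds) // 3
    ci = int(rng.integers(2, n_codons))  # skip start codon and stop codon
    codon = cds[3 * (ci - 1) : 3 * ci]
    offsets = list(rng.permutation(3))
    for off in offsets:
        ref = codon[off]
        for alt in rng.permutation([b for b in "ACGT" if b != ref]):
            alt_codon = codon[:off] + alt + codon[off + 1 :]
            ref_aa = translate_cds(codon)
            alt_aa = translate_cds(alt_codon)
            ok = (
                (effect == EFFECT_SUBSTITUTION and ref_aa != alt_aa and alt_aa != "X")
                or (effect == EFFECT_TRUNCATION and alt_aa == "X")
                or (effect == EFFECT_NONE and ref_aa == alt_aa)
            )
            if not ok:
                continue
            cds_position = 3 * (ci - 1) + off + 1
            gpos = _coding_to_genomic(feat, cds_position)
            g_ref, g_alt = ref, alt
            if feat.strand == "-":
                g_ref = g_ref.translate(_COMPLEMENT)
                g_alt = g_alt.translate(_COMPLEMENT)
            return Variant(feat.contig_id, gpos, g_ref, g_alt)
    return None


def generate_variants(
    genome: AnnotatedGenome,
    counts: Mapping[str, int],
    seed: int = 0,
) -> tuple[list[Variant], TruthTable]:
    """Sample point mutations realizing requested effect classes.

    ``counts`` maps effect class (Substitution/Truncation/None/Intergenic) to
    the number of variants wanted. Positions are distinct; an unrealizable
    class raises. Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    valid = {EFFECT_SUBSTITUTION, EFFECT_TRUNCATION, EFFECT_NONE, EFFECT_INTERGENIC}
    unknown = set(counts) - valid
    if unknown:
        raise ValueError(f"unknown effect classes {sorted(unknown)}")
    cds_feats = [f for f in genome.cds_features() if len(f) % 3 == 0]
    if any(counts.get(k, 0) for k in valid - {EFFECT_INTERGENIC}) and not cds_feats:
        raise ValueError("genome has no CDS features; coding classes unrealizable")
    in_cds: list[tuple[int, int]] = sorted(
        (f.start, f.end) for f in cds_feats
    )
    used: set[tuple[str, int]] = set()
    variants: list[Variant] = []
    truth: list[tuple[Variant, str]] = []

    for effect in (EFFECT_SUBSTITUTION, EFFECT_TRUNCATION, EFFECT_NONE):
        want = int(counts.get(effect, 0))
        made = 0
        attempts = 0
        while made < want:
            attempts += 1
            if attempts > 5000 * max(want, 1):
                raise ValueError(f"effect class {effect} unrealizable in this genome")
            feat = cds_feats[int(rng.integers(0, len(cds_feats)))]
            cds = "".join(
                genome.contigs[feat.contig_id][feat.start : feat.end]
            )
            if feat.strand == "-":
                cds = reverse_complement(cds)
            var = _plant_in_cds(rng, genome, feat, cds, effect)
            if var is None or (var.contig_id, var.genome_position) in used:
                continue
            # a position inside two overlapping CDS could classify differently
            overlapping = [
                f
                for f in genome.cds_features(var.contig_id)
                if f.start <= var.genome_position - 1 < f.end
            ]
            if len(overlapping) != 1:
                continue
            used.add((var.contig_id, var.genome_position))
            variants.append(var)
            truth.append((var, effect))
            made += 1

    want = int(counts.get(EFFECT_INTERGENIC, 0))
    made = 0
    attempts = 0
    contig_ids = sorted(genome.contigs)
    while made < want:
        attempts += 1
        if attempts > 5000 * max(want, 1):
            raise ValueError("no intergenic space available")
        cid = contig_ids[int(rng.integers(0, len(contig_ids)))]
        seq = genome.contigs[cid]
        pos0 = int(rng.integers(0, len(seq)))
        if any(
            f.start <= pos0 < f.end
            for f in genome.features
            if f.contig_id == cid
        ):
            continue
        if (cid, pos0 + 1) in used:
            continue
        ref = seq[pos0]
        if ref not in "ACGT":
            continue
        alt_choices = [b for b in "ACGT" if b != ref]
        alt = alt_choices[int(rng.integers(0, 3))]
        var = Variant(cid, pos0 + 1, ref, alt)
        used.add((cid, pos0 + 1))
        variants.append(var)
        truth.append((var, EFFECT_INTERGENIC))
        made += 1

    variants.sort(key=lambda v: (v.contig_id, v.genome_position))
    order = {(v.contig_id, v.genome_position): i for i, v in enumerate(variants)}
    truth.sort(key=lambda t: order[(t[0].contig_id, t[0].genome_position)])
    return variants, TruthTable(variant_classes=truth)


# ---------------------------------------------------------------------------
# Cq tables


def generate_cq_table(
    true_ratios: Mapping[str, Mapping[str, float]],
    efficiencies: Mapping[str, float],
    noise_sd: float = 0.15,
    replicates: int = 2,
    seed: int = 0,
    reference_target: str = "gapC",
    calibrator_sample: str = "calibrator",
) -> tuple[CqTable, TruthTable]:
    """Invert the efficiency-corrected ddCq relation into a noisy Cq table.

    ``true_ratios`` maps sample -> target -> fold change relative to the
    calibrator (which is added automatically with ratio 1 everywhere).
    Gaussian noise of sd ``noise_sd`` cycles is added independently to every
    replicate Cq; with ``noise_sd=0`` the quantification recovers the true
    ratios exactly.
    """
    rng = np.random.default_rng(seed)
    targets = sorted({t for m in true_ratios.values() for t in m})
    for s, m in true_ratios.items():
        for t, r in m.items():
            if r <= 0:
                raise ValueError(f"true ratio must be > 0 (sample {s}, target {t})")
    effs = dict(efficiencies)
    effs.setdefault(reference_target, 2.0)
    for t in targets:
        if t not in effs:
            raise ValueError(f"no efficiency for target {t!r}")
    samples = [calibrator_sample] + sorted(true_ratios)
    base_ref = 20.0
    base_target = {t: 22.0 + 4.0 * rng.random() for t in targets}
    rows = []
    truth_ratios: dict[tuple[str, str], float] = {}
    for s in samples:
        delta = 0.0 if s == calibrator_sample else float(rng.uniform(-0.5, 0.5))
        ref_cq = base_ref + delta
        for rep in range(1, replicates + 1):
            rows.append(
                {
                    "sample": s,
                    "target": reference_target,
                    "replicate": rep,
                    "cq": ref_cq + float(rng.normal(0.0, noise_sd)) if noise_sd else ref_cq,
                }
            )
        for t in targets:
            ratio = 1.0 if s == calibrator_sample else float(true_ratios[s].get(t, 1.0))
            truth_ratios[(s, t)] = ratio
            e_t, e_ref = effs[t], effs[reference_target]
            cq = base_target[t] - (math.log(ratio) - delta * math.log(e_ref)) / math.log(e_t)
            for rep in range(1, replicates + 1):
                rows.append(
                    {
                        "sample": s,
                        "target": t,
                        "replicate": rep,
                        "cq": cq + float(rng.normal(0.0, noise_sd)) if noise_sd else cq,
                    }
                )
    table = CqTable(
        data=pd.DataFrame(rows),
        efficiencies=effs,
        reference_target=reference_target,
        calibrator_sample=calibrator_sample,
    )
    return table, TruthTable(true_ratios=truth_ratios, efficiencies=effs)


# ---------------------------------------------------------------------------
# Multi-genome families


def generate_genome_family(
    config: GenomeSimConfig,
    statuses: Sequence[Sequence[str]],
    labels: Sequence[str] | None = None,
) -> tuple[list[AnnotatedGenome], list[TruthTable], TruthTable]:
    """A query genome plus derived strains with prescribed conservation.

    ``statuses[k]`` prescribes, for target genome k, one status per regulon
    unit of the query: ``conserved-with-motif`` keeps the unit genes and
    their planted motif, ``conserved-gene-only`` keeps the genes but drops
    the motif, ``absent`` drops the unit genes entirely. Orthologs are exact
    sequence copies under fresh locus tags, so reciprocal-best-hit mapping
    recovers the correspondence. Returns ([query, *targets], per-genome
    truths, family truth keyed by the query's unit lead genes).
    """
    from .conservation import ABSENT, CONSERVED_GENE_ONLY, CONSERVED_WITH_MOTIF

    valid = {CONSERVED_WITH_MOTIF, CONSERVED_GENE_ONLY, ABSENT}
    for sl in statuses:
        if len(sl) != config.n_regulon_units:
            raise ValueError("one status per regulon unit required")
        if set(sl) - valid:
            raise ValueError(f"unknown statuses {set(sl) - valid}")
    if labels is None:
        labels = ["strainA"] + [f"strain{chr(66 + k)}" for k in range(len(statuses))]

    rng = np.random.default_rng(config.seed)
    pattern = ConsensusPattern(config.pattern)
    query_blocks = _make_block_specs(config, rng, labels[0])
    contigs, features, units, cds_truth = _build_contigs(query_blocks, config, rng)
    if config.motif_free_background:
        contigs = _scrub_background(contigs, features, units, pattern, rng, config.gc_content)
    query = AnnotatedGenome(contigs=contigs, features=features, source_label=labels[0])
    # clone from the scrubbed sequences so orthologs stay (near-)identical
    cds_truth = _extract_all_cds(query)
    for b in query_blocks:
        for g in b.genes:
            g.cds = cds_truth[g.gene_id]
        if b.ebp is not None:
            b.ebp.cds = cds_truth[b.ebp.gene_id]
    # map unit lead -> block index for status application
    unit_order = [u.lead_gene for u in units]
    lead_to_block = {}
    for bi, b in enumerate(query_blocks):
        if b.motif_seq is not None:
            lead_to_block[b.genes[0].gene_id] = bi

    genomes = [query]
    truths = [TruthTable(units=units, cds_sequences=cds_truth)]
    family: dict[str, dict[str, str]] = {lead: {} for lead in unit_order}
    ortho_suffix: dict[str, dict[str, str]] = {}

    for k, status_list in enumerate(statuses):
        label = labels[k + 1]
        status_by_lead = dict(zip(unit_order, status_list))
        new_blocks: list[_BlockSpec] = []
        id_map: dict[str, str] = {}

        def clone_gene(g: _GeneSpec) -> _GeneSpec:
            nid = label + g.gene_id[g.gene_id.index("_") :]
            id_map[g.gene_id] = nid
            return _GeneSpec(nid, g.cds, g.product)

        for b in query_blocks:
            if b.motif_seq is None:
                new_blocks.append(
                    replace(b, genes=[clone_gene(g) for g in b.genes])
                )
                continue
            status = status_by_lead[b.genes[0].gene_id]
            if status == ABSENT:
                continue
            nb = replace(
                b,
                genes=[clone_gene(g) for g in b.genes],
                ebp=clone_gene(b.ebp) if b.ebp else None,
                motif_seq=(
                    _motif_instance(rng, pattern)
                    if status == CONSERVED_WITH_MOTIF
                    else None
                ),
            )
            new_blocks.append(nb)
        contigs_k, feats_k, units_k, _ = _build_contigs(new_blocks, config, rng)
        if config.motif_free_background:
            contigs_k = _scrub_background(contigs_k, feats_k, units_k, pattern, rng, config.gc_content)
        gk = AnnotatedGenome(contigs=contigs_k, features=feats_k, source_label=label)
        genomes.append(gk)
        truths.append(TruthTable(units=units_k, cds_sequences=_extract_all_cds(gk)))
        for lead in unit_order:
            family[lead][label] = status_by_lead[lead]
        ortho_suffix[label] = id_map

    family_truth = TruthTable(conservation=family)
    return genomes, truths, family_truth
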