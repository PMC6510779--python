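"""Exact IUPAC consensus scanning and sigma-54 regulon assignment.

The sigma-54 holoenzyme binds a bipartite -24/-12 promoter element whose
consensus, distilled from compilations of validated promoters, is
``TGGCANNNNNNTTGCW``. Scanning is exact (no mismatches): a window matches
when every base falls in the allowed set of the corresponding consensus
position. Genes are called putatively sigma-54 regulated when a motif lies
within a fixed upstream window (default 500 bp) of their CDS start on the
same strand; assigned genes are extended into transcriptional units by an
intergenic-gap operon heuristic and flagged when an enhancer-binding-protein
(EBP) gene lies nearby — sigma-54 transcription strictly requires an EBP
activator.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd
from Bio.Data import IUPACData

from .genome import AnnotatedGenome, Feature, reverse_complement

__all__ = [
    "SIGMA54_CONSENSUS",
    "DEFAULT_EBP_KEYWORDS",
    "ConsensusPattern",
    "MotifHit",
    "RegulonAssignment",
    "ScanStatistics",
    "scan_consensus",
    "assign_regulon",
    "extend_operon",
    "flag_ebp_vicinity",
    "scan_statistics",
    "hits_to_bed",
    "hits_to_frame",
    "regulon_report",
]

SIGMA54_CONSENSUS = "TGGCANNNNNNTTGCW"

DEFAULT_EBP_KEYWORDS = ("sigma-54 dependent", "enhancer", "PAS", "AAA")

_IUPAC_SETS = {
    code.upper(): frozenset(bases.upper())
    for code, bases in IUPACData.ambiguous_dna_values.items()
}


class ConsensusPattern:
    """An IUPAC degenerate consensus with per-position allowed-base sets."""

    def __init__(self, pattern: str = SIGMA54_CONSENSUS):
        pattern = pattern.upper()
        for i, ch in enumerate(pattern):
            if ch not in _IUPAC_SETS:
                raise ValueError(
                    f"invalid IUPAC code {ch!r} at pattern position {i + 1}"
                )
        self.pattern = pattern
        self.allowed: tuple[frozenset[str], ...] = tuple(
            _IUPAC_SETS[ch] for ch in pattern
        )
        # overlapping matches via lookahead; genome N never matches (N is not
        # in any allowed set expansion, which is deliberate)
        self._fwd = re.compile(
            "(?=(" + "".join("[" + "".join(sorted(s)) + "]" for s in self.allowed) + "))"
        )
        rc = reverse_complement(pattern)
        self._rev = re.compile(
            "(?=("
            + "".join("[" + "".join(sorted(_IUPAC_SETS[ch])) + "]" for ch in rc)
            + "))"
        )

    def __len__(self) -> int:
        return len(self.pattern)

    def matches(self, window: str) -> bool:
        window = window.upper()
        return len(window) == len(self.pattern) and all(
            b in s for b, s in zip(window, self.allowed)
        )

    @property
    def match_probability(self) -> float:
        """Per-window match probability under i.i.d. equal-frequency bases."""
        return math.prod(len(s) / 4.0 for s in self.allowed)


@dataclass(frozen=True)
class MotifHit:
    """One located consensus occurrence, in forward-genomic coordinates.

    ``matched`` is the motif-strand (coding-orientation) sequence, so it
    satisfies the consensus position-wise for both + and - hits.
    """

    contig_id: str
    start: int
    end: int
    strand: Literal["+", "-"]
    matched: str


@dataclass
class RegulonAssignment:
    """A motif hit linked to its downstream transcriptional unit."""

    hit: MotifHit
    gene_id: str | None
    distance: int | None  # bp from motif 3' end to CDS start, 0..window
    transcriptional_unit: list[str] = field(default_factory=list)
    alternatives: list[tuple[int, str]] = field(default_factory=list)  # (distance, gene)
    overlaps_cds: bool = False
    ebp_nearby: bool = False
    ebp_gene_id: str | None = None

    @property
    def assigned(self) -> bool:
        return self.gene_id is not None


@dataclass(frozen=True)
class ScanStatistics:
    """Observed hit count against the i.i.d.-background analytic expectation."""

    n_hits: int
    genome_length: int
    expected_hits_random: float
    enrichment_ratio: float


def scan_consensus(
    genome: AnnotatedGenome,
    pattern: ConsensusPattern | str = SIGMA54_CONSENSUS,
    strands: Literal["both", "+", "-"] = "both",
) -> list[MotifHit]:
    """All exact occurrences of the consensus on the requested strands.

    Overlapping occurrences are all reported; minus-strand hits carry
    forward-genomic coordinates with ``strand == "-"``. Sorted by
    (contig, start, strand).
    """
    if isinstance(pattern, str):
        pattern = ConsensusPattern(pattern)
    hits: list[MotifHit] = []
    k = len(pattern)
    for cid in sorted(genome.contigs):
        seq = genome.contigs[cid]
        if strands in ("both", "+"):
            for m in pattern._fwd.finditer(seq):
                hits.append(MotifHit(cid, m.start(), m.start() + k, "+", m.group(1)))
        if strands in ("both", "-"):
            for m in pattern._rev.finditer(seq):
                hits.append(
                    MotifHit(
                        cid,
                        m.start(),
                        m.start() + k,
                        "-",
                        reverse_complement(m.group(1)),
                    )
                )
    hits.sort(key=lambda h: (h.contig_id, h.start, h.strand))
    return hits


def _cds_sorted(genome: AnnotatedGenome, contig_id: str) -> list[Feature]:
    return sorted(genome.cds_features(contig_id), key=lambda f: (f.start, f.feature_id))


def assign_regulon(
    hits: Sequence[MotifHit],
    genome: AnnotatedGenome,
    window: int = 500,
    max_gap: int = 50,
) -> list[RegulonAssignment]:
    """Associate each motif hit with the nearest downstream CDS start.

    Assignment is strand-matched (the -24/-12 element is directional and the
    consensus non-palindromic): a + hit can only drive a + gene to its right,
    a - hit a - gene to its left. ``distance`` runs from the motif 3' end
    (promoter-proximal edge in gene orientation) to the CDS start, inclusive
    window [0, window]. Nearest start wins; other in-window candidates are
    listed as alternatives. Each assignment's transcriptional unit is the
    operon extension of the assigned gene. Hits with no in-window CDS are
    returned unassigned.
    """
    assignments: list[RegulonAssignment] = []
    for hit in hits:
        cds = _cds_sorted(genome, hit.contig_id)
        candidates: list[tuple[int, str]] = []
        for feat in cds:
            if feat.strand != hit.strand:
                continue
            if hit.strand == "+":
                d = feat.start - hit.end
            else:
                d = hit.start - feat.end
            if 0 <= d <= window:
                candidates.append((d, feat.feature_id))
        candidates.sort()
        overlaps = any(
            feat.start < hit.end and hit.start < feat.end for feat in cds
        )
        if candidates:
            d, gid = candidates[0]
            assignments.append(
                RegulonAssignment(
                    hit=hit,
                    gene_id=gid,
                    distance=d,
                    transcriptional_unit=extend_operon(genome, gid, max_gap=max_gap),
                    alternatives=candidates[1:],
                    overlaps_cds=overlaps,
                )
            )
        else:
            assignments.append(
                RegulonAssignment(hit=hit, gene_id=None, distance=None,
                                  overlaps_cds=overlaps)
            )
    return assignments


def extend_operon(
    genome: AnnotatedGenome, gene_id: str, max_gap: int = 50
) -> list[str]:
    """Maximal co-directional run of consecutive CDS downstream of a gene.

    Walks the contig's CDS in gene orientation starting at ``gene_id`` and
    keeps extending while the next CDS shares the strand and the intergenic
    gap is at most ``max_gap`` bp; any opposite-strand gene in between breaks
    the run.
    """
    lead = genome.feature(gene_id)
    cds = _cds_sorted(genome, lead.contig_id)
    idx = next(i for i, f in enumerate(cds) if f.feature_id == gene_id)
    unit = [gene_id]
    if lead.strand == "+":
        cur = cds[idx]
        for nxt in cds[idx + 1 :]:
            if nxt.strand != cur.strand or nxt.start - cur.end > max_gap:
                break
            unit.append(nxt.feature_id)
            cur = nxt
    else:
        cur = cds[idx]
        for nxt in reversed(cds[:idx]):
            if nxt.strand != cur.strand or cur.start - nxt.end > max_gap:
                break
            unit.append(nxt.feature_id)
            cur = nxt
    return unit


def flag_ebp_vicinity(
    assignment: RegulonAssignment,
    genome: AnnotatedGenome,
    keywords: Iterable[str] = DEFAULT_EBP_KEYWORDS,
    span: int = 5000,
) -> RegulonAssignment:
    """Set ``ebp_nearby`` when an EBP-annotated gene flanks the unit.

    A feature counts when its product annotation matches any keyword
    (case-insensitive) and it lies within ``span`` bp of the transcriptional
    unit's genomic extent, unit members excluded.
    """
    keywords = [k.lower() for k in keywords]
    if not keywords:
        raise ValueError("keywords must be non-empty")
    if not assignment.assigned:
        return assignment
    members = set(assignment.transcriptional_unit)
    feats = [genome.feature(g) for g in members]
    lo = min(f.start for f in feats)
    hi = max(f.end for f in feats)
    contig = feats[0].contig_id
    for feat in genome.features:
        if feat.contig_id != contig or feat.feature_id in members:
            continue
        product = feat.product.lower()
        if not any(k in product for k in keywords):
            continue
        if feat.end >= lo - span and feat.start <= hi + span:
            assignment.ebp_nearby = True
            assignment.ebp_gene_id = feat.feature_id
            return assignment
    assignment.ebp_nearby = False
    assignment.ebp_gene_id = None
    return assignment


def scan_statistics(
    hits: Sequence[MotifHit],
    genome: AnnotatedGenome,
    pattern: ConsensusPattern | str = SIGMA54_CONSENSUS,
) -> ScanStatistics:
    """Hit count vs the closed-form expectation on i.i.d. uniform sequence.

    expected = 2 * sum_contigs (L - k + 1) * prod_positions |allowed|/4;
    for the default 16-mer the per-window-per-strand probability is
    (1/4)^9 * (1/2) = 1/524288.
    """
    if isinstance(pattern, str):
        pattern = ConsensusPattern(pattern)
    k = len(pattern)
    p = pattern.match_probability
    windows = sum(max(0, len(s) - k + 1) for s in genome.contigs.values())
    expected = 2.0 * windows * p
    n = len(hits)
    return ScanStatistics(
        n_hits=n,
        genome_length=genome.total_length,
        expected_hits_random=expected,
        enrichment_ratio=n / expected if expected > 0 else math.inf,
    )


# ---------------------------------------------------------------------------
# Report writers


def hits_to_bed(hits: Sequence[MotifHit], path: str | Path) -> None:
    """BED6 (0-based half-open, score 0)."""
    with open(path, "w") as fh:
        for i, h in enumerate(hits):
            fh.write(
                f"{h.contig_id}\t{h.start}\t{h.end}\tsigma54_site_{i + 1}\t0\t{h.strand}\n"
            )


def hits_to_frame(hits: Sequence[MotifHit]) -> pd.DataFrame:
    """Hit table with 1-based inclusive coordinates for reports."""
    return pd.DataFrame(
        {
            "contig": [h.contig_id for h in hits],
            "start": [h.start + 1 for h in hits],
            "end": [h.end for h in hits],
            "strand": [h.strand for h in hits],
            "matched": [h.matched for h in hits],
        }
    )


def regulon_report(assignments: Sequence[RegulonAssignment]) -> pd.DataFrame:
    rows = []
    for a in assignments:
        rows.append(
            {
                "contig": a.hit.contig_id,
                "motif_start": a.hit.start + 1,
                "motif_end": a.hit.end,
                "strand": a.hit.strand,
                "matched": a.hit.matched,
                "gene": a.gene_id or "unassigned",
                "distance": a.distance if a.distance is not None else "",
                "transcriptional_unit": "-".join(a.transcriptional_unit),
                "alternatives": ";".join(f"{g}:{d}" for d, g in a.alternatives),
                "overlaps_cds": a.overlaps_cds,
                "ebp_nearby": a.ebp_nearby,
                "ebp_gene": a.ebp_gene_id or "",
            }
        )
    return pd.DataFrame(rows)
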