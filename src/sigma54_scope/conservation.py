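"""Cross-genome regulon conservation via reciprocal-best-hit orthology.

A desk-scale stand-in for web synteny browsers: proteomes are compared
all-vs-all with Smith-Waterman local alignment (BLOSUM62, affine gaps) and
reduced to reciprocal best pairs; each predicted transcriptional unit of a
query regulon is then classified in a target genome as conserved with its
motif, conserved as a gene only, or absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .genome import AnnotatedGenome, extract_cds, translate_cds
from .motifs import RegulonAssignment

__all__ = [
    "AlignmentScoring",
    "OrthologMap",
    "ConservationReport",
    "proteome",
    "reciprocal_best_hits",
    "compare_regulons",
    "read_ortholog_table",
    "write_ortholog_table",
]

CONSERVED_WITH_MOTIF = "conserved-with-motif"
CONSERVED_GENE_ONLY = "conserved-gene-only"
ABSENT = "absent"


@dataclass(frozen=True)
class AlignmentScoring:
    """Protein local-alignment scoring (BLOSUM62, gap open 11 / extend 1)."""

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    min_score: float = 50.0

    def aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = substitution_matrices.load(self.matrix)
        aligner.open_gap_score = -self.gap_open
        aligner.extend_gap_score = -self.gap_extend
        return aligner


@dataclass
class OrthologMap:
    """Reciprocal best-scoring gene pairs between two proteomes."""

    pairs: list[tuple[str, str, float]]
    unmatched_a: list[str] = field(default_factory=list)
    unmatched_b: list[str] = field(default_factory=list)

    def a_to_b(self) -> dict[str, str]:
        return {a: b for a, b, _ in self.pairs}

    def b_to_a(self) -> dict[str, str]:
        return {b: a for a, b, _ in self.pairs}


@dataclass
class ConservationReport:
    """Per-transcriptional-unit conservation status in one target strain."""

    query_label: str
    target_label: str
    statuses: dict[str, str]  # unit lead gene id -> status

    def counts(self) -> dict[str, int]:
        out = {CONSERVED_WITH_MOTIF: 0, CONSERVED_GENE_ONLY: 0, ABSENT: 0}
        for s in self.statuses.values():
            out[s] += 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "unit": list(self.statuses),
                "status": list(self.statuses.values()),
                "query": self.query_label,
                "target": self.target_label,
            }
        )


def proteome(genome: AnnotatedGenome) -> dict[str, str]:
    """Translated CDS set (terminal stop sentinel stripped)."""
    prots = {}
    for feat in genome.cds_features():
        if len(feat) % 3:
            continue  # un-translatable CDS are not comparable
        aa = translate_cds(extract_cds(genome, feat.feature_id))
        prots[feat.feature_id] = aa.rstrip("X") or aa
    return prots


def _best_hits(
    queries: Mapping[str, str],
    targets: Mapping[str, str],
    scoring: AlignmentScoring,
) -> dict[str, tuple[str, float]]:
    aligner = scoring.aligner()
    best: dict[str, tuple[str, float]] = {}
    for qid, qseq in queries.items():
        top_id: str | None = None
        top_score = -1.0
        top_len = -1
        for tid in sorted(targets):
            score = aligner.score(qseq, targets[tid])
            if score > top_score:
                top_id, top_score, top_len = tid, score, -1
            elif score == top_score and top_id is not None:
                # tie: longer alignment wins, then lexicographic id
                if top_len < 0:
                    top_len = _aln_length(aligner, qseq, targets[top_id])
                cand_len = _aln_length(aligner, qseq, targets[tid])
                if cand_len > top_len or (cand_len == top_len and tid < top_id):
                    top_id, top_len = tid, cand_len
        if top_id is not None and top_score >= scoring.min_score:
            best[qid] = (top_id, top_score)
    return best


def _aln_length(aligner: Align.PairwiseAligner, a: str, b: str) -> int:
    aln = next(iter(aligner.align(a, b)))
    return aln.length


def reciprocal_best_hits(
    proteome_a: Mapping[str, str],
    proteome_b: Mapping[str, str],
    scoring: AlignmentScoring = AlignmentScoring(),
) -> OrthologMap:
    """Mutual best-scoring pairs between two translated CDS sets.

    Ties are broken by longer alignment then lexicographic gene id; pairs
    below ``scoring.min_score`` are dropped.
    """
    if not proteome_a or not proteome_b:
        raise ValueError("empty proteome")
    fwd = _best_hits(proteome_a, proteome_b, scoring)
    rev = _best_hits(proteome_b, proteome_a, scoring)
    pairs = []
    for a, (b, score) in sorted(fwd.items()):
        if rev.get(b, (None,))[0] == a:
            pairs.append((a, b, score))
    matched_a = {a for a, _, _ in pairs}
    matched_b = {b for _, b, _ in pairs}
    return OrthologMap(
        pairs=pairs,
        unmatched_a=sorted(set(proteome_a) - matched_a),
        unmatched_b=sorted(set(proteome_b) - matched_b),
    )


def compare_regulons(
    regulon_a: Sequence[RegulonAssignment],
    regulon_b: Sequence[RegulonAssignment],
    ortholog_map: OrthologMap,
    query_label: str = "A",
    target_label: str = "B",
) -> ConservationReport:
    """Classify each query unit's conservation in the target genome.

    A unit is matched when at least one member gene has an ortholog
    (single-linkage through its members); it is conserved-with-motif when
    some member's ortholog belongs to a motif-assigned unit of the target
    regulon, conserved-gene-only when orthologs exist outside the target
    regulon, absent when no member has an ortholog.
    """
    a2b = ortholog_map.a_to_b()
    known_b = set(ortholog_map.b_to_a()) | set(ortholog_map.unmatched_b)
    covered_b: set[str] = set()
    for asg in regulon_b:
        if asg.assigned:
            covered_b.add(asg.gene_id)  # type: ignore[arg-type]
            covered_b.update(asg.transcriptional_unit)
    statuses: dict[str, str] = {}
    for asg in regulon_a:
        if not asg.assigned:
            continue
        lead = asg.gene_id
        assert lead is not None
        orthologs = [a2b[g] for g in asg.transcriptional_unit if g in a2b]
        for o in orthologs:
            if o not in known_b and known_b:
                raise KeyError(f"ortholog map references unknown target gene {o!r}")
        if not orthologs:
            statuses[lead] = ABSENT
        elif any(o in covered_b for o in orthologs):
            statuses[lead] = CONSERVED_WITH_MOTIF
        else:
            statuses[lead] = CONSERVED_GENE_ONLY
    return ConservationReport(query_label, target_label, statuses)


def write_ortholog_table(ortholog_map: OrthologMap, path: str | Path) -> None:
    pd.DataFrame(
        ortholog_map.pairs, columns=["gene_a", "gene_b", "score"]
    ).to_csv(path, sep="\t", index=False)


def read_ortholog_table(path: str | Path) -> OrthologMap:
    """External ortholog table (gene_a, gene_b, score TSV) overriding RBH."""
    df = pd.read_csv(path, sep="\t")
    pairs = [
        (str(r.gene_a), str(r.gene_b), float(getattr(r, "score", 0.0)))
        for r in df.itertuples()
    ]
    return OrthologMap(pairs=pairs)
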