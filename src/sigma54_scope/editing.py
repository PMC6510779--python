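"""Deletion-editing arithmetic for CRISPR/Cas9 genome engineering designs.

Covers the in-silico bookkeeping around a markerless deletion: applying the
deletion to an annotated genome (with feature coordinate shifts), predicting
colony-PCR band sizes with an exact-match primer model, enumerating SpCas9
protospacers (NGG PAM) whose cut site falls in the targeted interval, and
computing the residual ORF length left after the deletion (frameshifts
naturally run into early stops).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

from .genome import AnnotatedGenome, Feature, reverse_complement, translate_cds
from .genome import STOP_SENTINEL

__all__ = [
    "DeletionDesign",
    "PrimerPair",
    "Protospacer",
    "apply_deletion",
    "in_silico_pcr",
    "enumerate_protospacers",
    "residual_orf",
]


@dataclass(frozen=True)
class DeletionDesign:
    """A genomic span to remove, with optional flanking homology arms.

    All intervals 0-based half-open. Homology arms, when given, must abut the
    deleted interval on each side without overlapping it.
    """

    contig_id: str
    start: int
    end: int
    left_arm: tuple[int, int] | None = None
    right_arm: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"bad deletion interval [{self.start}, {self.end})")
        if self.left_arm is not None and self.left_arm[1] != self.start:
            raise ValueError("left homology arm must abut the deletion start")
        if self.right_arm is not None and self.right_arm[0] != self.end:
            raise ValueError("right homology arm must abut the deletion end")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PrimerPair:
    """Exact-match PCR primers; forward anneals to +, reverse to -."""

    forward: str
    reverse: str
    forward_name: str = "fwd"
    reverse_name: str = "rev"

    def __post_init__(self) -> None:
        for name, seq in ((self.forward_name, self.forward), (self.reverse_name, self.reverse)):
            if len(seq) < 12:
                raise ValueError(f"primer {name} shorter than 12 nt")
        object.__setattr__(self, "forward", self.forward.upper())
        object.__setattr__(self, "reverse", self.reverse.upper())


@dataclass(frozen=True)
class Protospacer:
    """A 20-mer SpCas9 target with its NGG PAM.

    ``position`` is the 0-based genomic start of the protospacer site on the
    forward strand; ``cut_position`` the 0-based boundary of the blunt cut,
    3 bp 5' of the PAM.
    """

    sequence: str
    strand: Literal["+", "-"]
    position: int
    pam: str
    cut_position: int

    def __post_init__(self) -> None:
        if len(self.sequence) != 20:
            raise ValueError("protospacer must be 20 nt")
        if len(self.pam) != 3 or self.pam[1:] != "GG":
            raise ValueError(f"PAM {self.pam!r} does not match NGG")


def apply_deletion(genome: AnnotatedGenome, design: DeletionDesign) -> AnnotatedGenome:
    """Remove the designed interval, shifting/truncating downstream features.

    Features wholly inside the deletion are dropped; features overlapping a
    breakpoint are truncated and their id suffixed ``_truncated``; features
    downstream shift left by the deletion length. The edited contig is
    shorter by exactly ``design.length``.
    """
    if design.contig_id not in genome.contigs:
        raise ValueError(f"unknown contig {design.contig_id!r}")
    seq = genome.contigs[design.contig_id]
    if design.end > len(seq):
        raise ValueError(
            f"deletion [{design.start}, {design.end}) outside contig of length {len(seq)}"
        )
    dlen = design.length
    contigs = dict(genome.contigs)
    contigs[design.contig_id] = seq[: design.start] + seq[design.end :]
    feats: list[Feature] = []
    for f in genome.features:
        if f.contig_id != design.contig_id:
            feats.append(f)
            continue
        if f.end <= design.start:
            feats.append(f)
        elif f.start >= design.end:
            feats.append(replace(f, start=f.start - dlen, end=f.end - dlen))
        elif f.start >= design.start and f.end <= design.end:
            continue  # feature removed entirely
        else:
            ns = min(f.start, design.start)
            ne = max(f.end, design.end) - dlen
            if f.start > design.start:
                ns = design.start
            feats.append(
                replace(f, feature_id=f.feature_id + "_truncated", start=ns, end=ne)
            )
    return AnnotatedGenome(
        contigs=contigs,
        features=feats,
        source_label=(genome.source_label + " edited").strip(),
    )


def _find_all(haystack: str, needle: str) -> list[int]:
    sites, i = [], haystack.find(needle)
    while i != -1:
        sites.append(i)
        i = haystack.find(needle, i + 1)
    return sites


def in_silico_pcr(
    genome: AnnotatedGenome, primers: PrimerPair, contig_id: str | None = None
) -> tuple[int, str]:
    """Predicted amplicon (length, sequence) under exact primer binding.

    The forward primer must bind the + strand exactly once, the reverse
    primer's reverse complement must occur once downstream of it; amplicon
    length runs from the forward 5' end to the reverse 5' end inclusive.
    Zero or multiple binding sites are errors listing what was found.
    """
    contig_ids = [contig_id] if contig_id else sorted(genome.contigs)
    amplicons = []
    for cid in contig_ids:
        seq = genome.contigs[cid]
        fwd_sites = _find_all(seq, primers.forward)
        rev_sites = _find_all(seq, reverse_complement(primers.reverse))
        if not fwd_sites and not rev_sites:
            continue
        if len(fwd_sites) != 1 or len(rev_sites) != 1:
            raise ValueError(
                f"ambiguous primer binding on {cid}: forward at {fwd_sites}, "
                f"reverse-complement at {rev_sites}"
            )
        fstart = fwd_sites[0]
        rend = rev_sites[0] + len(primers.reverse)
        if rend <= fstart:
            raise ValueError(
                f"primers face away from each other on {cid} "
                f"(forward at {fstart}, reverse site ends at {rend})"
            )
        amplicons.append(seq[fstart:rend])
    if not amplicons:
        raise ValueError("no primer binding sites found on any contig")
    if len(amplicons) > 1:
        raise ValueError("primer pair amplifies on multiple contigs")
    return len(amplicons[0]), amplicons[0]


def enumerate_protospacers(
    genome: AnnotatedGenome,
    contig_id: str,
    interval: tuple[int, int],
    pam: str = "NGG",
    length: int = 20,
) -> list[Protospacer]:
    """All SpCas9 protospacers whose blunt cut falls inside the interval.

    Both strands are scanned for ``length``-mers followed 3' by an NGG PAM;
    the cut site is modeled 3 bp 5' of the PAM (between protospacer positions
    17 and 18). The interval is 0-based half-open; a cut boundary c qualifies
    when start < c < end. Sorted by genomic position.
    """
    if pam.upper() != "NGG":
        raise ValueError("only the SpCas9 NGG PAM is supported")
    seq = genome.contigs[contig_id]
    lo, hi = interval
    out: list[Protospacer] = []
    for i in range(0, len(seq) - length - 2):
        if seq[i + length + 1 : i + length + 3] == "GG":
            cut = i + length - 3  # boundary 3 bp 5' of PAM
            if lo < cut < hi:
                out.append(
                    Protospacer(
                        sequence=seq[i : i + length],
                        strand="+",
                        position=i,
                        pam=seq[i + length : i + length + 3],
                        cut_position=cut,
                    )
                )
    # minus strand: site seq[j:j+length] is the reverse complement of the
    # protospacer; the PAM sits immediately 5' in genome coordinates (CCN)
    for j in range(3, len(seq) - length + 1):
        if seq[j - 3 : j - 1] == "CC":
            cut = j + 3
            if lo < cut < hi:
                out.append(
                    Protospacer(
                        sequence=reverse_complement(seq[j : j + length]),
                        strand="-",
                        position=j,
                        pam=reverse_complement(seq[j - 3 : j]),
                        cut_position=cut,
                    )
                )
    out.sort(key=lambda p: (p.position, p.strand))
    return out


def residual_orf(cds_sequence: str, deletion: tuple[int, int]) -> int:
    """Residue count before the first stop after splicing a deletion out.

    ``deletion`` is 0-based half-open in CDS coordinates. Translation starts
    at the original start codon; the count excludes the stop itself. A
    deletion removing any base of the start codon leaves no ORF and raises
    ValueError.
    """
    lo, hi = deletion
    if not (0 <= lo <= hi <= len(cds_sequence)):
        raise ValueError(f"deletion [{lo}, {hi}) outside CDS of length {len(cds_sequence)}")
    if lo < 3:
        raise ValueError("deletion removes the start codon: no ORF")
    spliced = cds_sequence[:lo] + cds_sequence[hi:]
    n = 0
    for i in range(0, len(spliced) - 2, 3):
        codon = spliced[i : i + 3]
        if translate_cds(codon) == STOP_SENTINEL:
            return n
        n += 1
    return n
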