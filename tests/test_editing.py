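"""Deletion application, in-silico PCR, protospacer enumeration, residual ORFs."""

from __future__ import annotations

import numpy as np
import pytest

from sigma54_scope.editing import (
    DeletionDesign,
    PrimerPair,
    apply_deletion,
    enumerate_protospacers,
    in_silico_pcr,
    residual_orf,
)
from sigma54_scope.genome import Feature, reverse_complement, translate_cds

from conftest import make_genome

BASES = np.array(list("ACGT"))


def random_seq(rng, n):
    return "".join(BASES[rng.integers(0, 4, n)])


class TestApplyDeletion:
    def test_contig_shortens_by_deletion_length(self):
        rng = np.random.default_rng(0)
        genome = make_genome(random_seq(rng, 10_000))
        edited = apply_deletion(genome, DeletionDesign("ctg", 4000, 4736))
        assert len(edited.contigs["ctg"]) == 9264

    def test_zero_length_deletion_is_identity(self):
        rng = np.random.default_rng(1)
        genome = make_genome(random_seq(rng, 500), [Feature("g", "ctg", 100, 250, "+")])
        edited = apply_deletion(genome, DeletionDesign("ctg", 300, 300))
        assert edited.contigs == genome.contigs
        assert edited.features[0].start == 100 and edited.features[0].end == 250

    def test_downstream_features_shift_by_hand_oracle(self):
        rng = np.random.default_rng(2)
        seq = random_seq(rng, 2000)
        feats = [
            Feature("up", "ctg", 50, 200, "+"),
            Feature("span", "ctg", 550, 800, "+"),
            Feature("inside", "ctg", 620, 680, "-"),
            Feature("down", "ctg", 900, 1100, "-"),
        ]
        genome = make_genome(seq, feats)
        edited = apply_deletion(genome, DeletionDesign("ctg", 600, 700))
        by_id = {f.feature_id: f for f in edited.features}
        assert (by_id["up"].start, by_id["up"].end) == (50, 200)
        assert "inside" not in by_id  # wholly deleted
        assert (by_id["down"].start, by_id["down"].end) == (800, 1000)
        tr = by_id["span_truncated"]
        assert (tr.start, tr.end) == (550, 700)  # 250 bp minus the 100 cut
        assert edited.contigs["ctg"] == seq[:600] + seq[700:]

    def test_out_of_bounds_rejected(self):
        genome = make_genome("ACGT" * 100)
        with pytest.raises(ValueError):
            apply_deletion(genome, DeletionDesign("ctg", 100, 500))

    def test_arms_must_abut(self):
        with pytest.raises(ValueError, match="abut"):
            DeletionDesign("ctg", 100, 200, left_arm=(0, 90))


class TestInSilicoPCR:
    def _locus(self, rng, fwd, rev, product_len):
        """Plant primers so the wild-type product has exactly product_len bp."""
        insert = random_seq(rng, product_len - len(fwd) - len(rev))
        amplicon = fwd + insert + reverse_complement(rev)
        return random_seq(rng, 800) + amplicon + random_seq(rng, 800), len(
            random_seq(rng, 0)
        )

    def test_band_sizes_before_and_after_deletion(self):
        rng = np.random.default_rng(3)
        fwd, rev = random_seq(rng, 22), random_seq(rng, 22)
        seq, _ = self._locus(rng, fwd, rev, 1406)
        genome = make_genome(seq)
        primers = PrimerPair(fwd, rev, "RH129", "RH130")
        length, _ = in_silico_pcr(genome, primers)
        assert length == 1406
        # delete 736 bp strictly inside the amplicon
        start = seq.find(fwd) + 300
        edited = apply_deletion(genome, DeletionDesign("ctg", start, start + 736))
        length2, _ = in_silico_pcr(edited, primers)
        assert length2 == 670

    def test_adjacent_facing_primers_minimal_product(self):
        rng = np.random.default_rng(4)
        fwd, rev = random_seq(rng, 18), random_seq(rng, 18)
        seq = random_seq(rng, 300) + fwd + reverse_complement(rev) + random_seq(rng, 300)
        length, amp = in_silico_pcr(make_genome(seq), PrimerPair(fwd, rev))
        assert length == len(fwd) + len(rev)
        assert amp == fwd + reverse_complement(rev)

    def test_random_placements_match_planted_arithmetic(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            fwd, rev = random_seq(rng, 20), random_seq(rng, 20)
            gap = int(rng.integers(0, 900))
            left, right = int(rng.integers(0, 400)), int(rng.integers(0, 400))
            seq = (
                random_seq(rng, left)
                + fwd
                + random_seq(rng, gap)
                + reverse_complement(rev)
                + random_seq(rng, right)
            )
            genome = make_genome(seq)
            length, amp = in_silico_pcr(genome, PrimerPair(fwd, rev))
            assert length == len(fwd) + gap + len(rev)
            assert amp == seq[left : left + length]

    def test_missing_site_is_error(self):
        rng = np.random.default_rng(6)
        genome = make_genome(random_seq(rng, 500))
        with pytest.raises(ValueError, match="no primer binding"):
            in_silico_pcr(genome, PrimerPair("A" * 30 + "CG", "T" * 30 + "GC"))

    def test_multiple_sites_listed(self):
        fwd = "ACGTACGTACGTACGTAA"
        rev = "TTGCATTGCATTGCATTG"
        seq = fwd + "C" * 50 + fwd + "C" * 50 + reverse_complement(rev)
        with pytest.raises(ValueError, match="ambiguous"):
            in_silico_pcr(make_genome(seq), PrimerPair(fwd, rev))

    def test_short_primer_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            PrimerPair("ACGTACGT", "ACGTACGTACGTAC")


class TestProtospacers:
    def brute(self, seq, lo, hi):
        out = []
        for i in range(len(seq)):
            if seq[i + 20 + 1 : i + 20 + 3] == "GG" and i + 23 <= len(seq):
                c = i + 17
                if lo < c < hi:
                    out.append((i, "+", seq[i : i + 20]))
            if i >= 3 and seq[i - 3 : i - 1] == "CC" and i + 20 <= len(seq):
                c = i + 3
                if lo < c < hi:
                    out.append((i, "-", reverse_complement(seq[i : i + 20])))
        return sorted(out)

    def test_constructed_forward_site(self):
        seq = "T" * 30 + "GATTACAGATTACAGATTAC" + "AGG" + "T" * 30
        genome = make_genome(seq)
        hits = enumerate_protospacers(genome, "ctg", (40, 60))
        fwd = [p for p in hits if p.strand == "+" and p.sequence == "GATTACAGATTACAGATTAC"]
        assert len(fwd) == 1
        assert fwd[0].pam == "AGG"
        assert fwd[0].cut_position == 30 + 17

    def test_no_gg_context_yields_empty(self):
        genome = make_genome("AT" * 200)
        assert enumerate_protospacers(genome, "ctg", (50, 350)) == []

    def test_matches_exhaustive_oracle_on_random_interval(self):
        rng = np.random.default_rng(7)
        seq = random_seq(rng, 2000)
        genome = make_genome(seq)
        lo, hi = 400, 1600
        got = sorted(
            (p.position, p.strand, p.sequence)
            for p in enumerate_protospacers(genome, "ctg", (lo, hi))
        )
        assert got == self.brute(seq, lo, hi)

    def test_every_protospacer_revalidates_pam(self):
        rng = np.random.default_rng(8)
        seq = random_seq(rng, 1000)
        for p in enumerate_protospacers(make_genome(seq), "ctg", (100, 900)):
            assert p.pam[1:] == "GG"
            if p.strand == "+":
                assert seq[p.position : p.position + 20] == p.sequence
                assert seq[p.position + 20 : p.position + 23] == p.pam
            else:
                assert reverse_complement(seq[p.position : p.position + 20]) == p.sequence
                assert reverse_complement(seq[p.position - 3 : p.position]) == p.pam


class TestResidualOrf:
    def test_in_frame_deletion_closed_form(self):
        # n-codon protein, k codons spliced out in frame, no new stop
        n, k = 120, 30
        cds = "ATG" + "GCA" * (n - 1) + "TAA"
        start = 3 * 10
        count = residual_orf(cds, (start, start + 3 * k))
        assert count == n - k

    def test_frameshift_to_13_residues(self):
        # a 463-codon protein whose 736 bp deletion frameshifts into a stop
        # at codon 14, leaving 13 residues
        rng = np.random.default_rng(9)
        codons = ["GCA"] * 464
        codons[0] = "ATG"
        codons[463] = "TAA"
        cds = list("".join(codons))
        del_start = 39  # right after codon 13
        del_len = 736
        # force a stop codon immediately after the splice junction
        stop_at = del_start + del_len
        cds[stop_at : stop_at + 3] = list("TAA")
        cds = "".join(cds)
        assert len(cds) == 464 * 3
        assert translate_cds(cds).index("X") == 463  # original ORF intact
        assert residual_orf(cds, (del_start, del_start + del_len)) == 13
        assert len(translate_cds(cds)) - 1 == 463

    def test_start_codon_removal_is_no_orf(self):
        cds = "ATG" + "GCA" * 10 + "TAA"
        with pytest.raises(ValueError, match="start codon"):
            residual_orf(cds, (0, 9))

    def test_random_pairs_vs_splice_translate_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(500):
            n = int(rng.integers(20, 200))
            cds = "ATG" + random_seq(rng, 3 * (n - 1)) + "TAA"
            lo = int(rng.integers(3, len(cds) - 1))
            hi = int(rng.integers(lo, len(cds) + 1))
            got = residual_orf(cds, (lo, hi))
            spliced = cds[:lo] + cds[hi:]
            expect = 0
            for i in range(0, len(spliced) - 2, 3):
                if spliced[i : i + 3] in ("TAA", "TAG", "TGA"):
                    break
                expect += 1
            assert got == expect
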