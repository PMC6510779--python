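"""Consensus scanning, regulon assignment, operon extension, EBP flags."""

from __future__ import annotations

import numpy as np
import pytest

from sigma54_scope.genome import AnnotatedGenome, Feature, reverse_complement
from sigma54_scope.motifs import (
    SIGMA54_CONSENSUS,
    ConsensusPattern,
    MotifHit,
    assign_regulon,
    extend_operon,
    flag_ebp_vicinity,
    scan_consensus,
    scan_statistics,
)
from sigma54_scope.simulate import GenomeSimConfig, generate_genome

from conftest import make_genome

BASES = np.array(list("ACGT"))


def brute_force_scan(seq: str, pattern: ConsensusPattern) -> list[tuple[int, str]]:
    """Position-by-position oracle over both strands; (start, strand) list."""
    k = len(pattern)
    out = []
    for i in range(len(seq) - k + 1):
        win = seq[i : i + k]
        if pattern.matches(win):
            out.append((i, "+"))
        if pattern.matches(reverse_complement(win)):
            out.append((i, "-"))
    return sorted(out)


class TestScanner:
    def test_single_forward_hit_at_position_3(self):
        seq = "AATGGCAAAAAAATTGCTAA"
        genome = make_genome(seq)
        hits = scan_consensus(genome)
        assert [(h.start + 1, h.strand) for h in hits] == [(3, "+")]
        assert hits[0].matched == seq[2:18]
        assert brute_force_scan(seq, ConsensusPattern()) == [(2, "+")]

    def test_all_c_sequence_has_no_hits(self):
        assert scan_consensus(make_genome("C" * 300)) == []

    def test_reverse_complement_plant_found_on_minus(self):
        site = "TGGCAGATTACTTGCA"
        planted = reverse_complement(site)
        seq = "CCCCC" + planted + "CCCCC"
        hits = scan_consensus(make_genome(seq))
        assert [(h.start, h.strand) for h in hits] == [(5, "-")]
        # matched sequence is reported in motif orientation
        assert ConsensusPattern().matches(hits[0].matched)

    def test_invalid_iupac_code_names_position(self):
        with pytest.raises(ValueError, match="position 3"):
            ConsensusPattern("TG!CA")

    def test_genome_n_never_matches(self):
        seq = "AATGGCANAAAAATTGCTAA"  # N inside the degenerate stretch
        assert scan_consensus(make_genome(seq)) == []

    def test_matches_brute_force_on_random_sequences(self):
        rng = np.random.default_rng(11)
        pattern = ConsensusPattern()
        for _ in range(100):
            n = int(rng.integers(30, 1200))
            seq = "".join(BASES[rng.integers(0, 4, n)])
            # spike some sequences with a planted site to exercise matches
            if rng.random() < 0.3 and n > 60:
                at = int(rng.integers(0, n - 16))
                seq = seq[:at] + "TGGCAGGGGGGTTGCA" + seq[at + 16 :]
            genome = make_genome(seq)
            got = sorted((h.start, h.strand) for h in scan_consensus(genome))
            assert got == brute_force_scan(seq, pattern)

    def test_overlapping_hits_all_reported(self):
        # two overlapping windows can both match through the N stretch
        seq = "TGGCATGGCAATTGCATTGCAA"
        pattern = ConsensusPattern()
        genome = make_genome(seq)
        got = sorted((h.start, h.strand) for h in scan_consensus(genome))
        assert got == brute_force_scan(seq, pattern)


class TestAssignment:
    def _genome_with_gene(self, gap: int, strand: str = "+"):
        rng = np.random.default_rng(5)
        motif = "TGGCAGATTACTTGCA"[:16]
        cds = "ATG" + "GCA" * 40 + "TAA"
        if strand == "+":
            seq = "C" * 100 + motif + "C" * gap + cds + "C" * 50
            feat = Feature("g1", "ctg", 116 + gap, 116 + gap + len(cds), "+")
        else:
            seq = "C" * 50 + reverse_complement(cds) + "C" * gap + reverse_complement(motif) + "C" * 100
            feat = Feature("g1", "ctg", 50, 50 + len(cds), "-")
        return make_genome(seq, [feat])

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_distance_measured_to_cds_start(self, strand):
        genome = self._genome_with_gene(120, strand)
        hits = scan_consensus(genome)
        assert len(hits) == 1 and hits[0].strand == strand
        (a,) = assign_regulon(hits, genome)
        assert a.gene_id == "g1"
        assert a.distance == 120

    def test_window_boundary_inclusive_at_500(self):
        genome = self._genome_with_gene(500)
        (a,) = assign_regulon(scan_consensus(genome), genome)
        assert a.assigned and a.distance == 500

    def test_501_bp_upstream_is_unassigned(self):
        genome = self._genome_with_gene(501)
        (a,) = assign_regulon(scan_consensus(genome), genome)
        assert not a.assigned and a.distance is None

    def test_strand_mismatch_not_assigned(self):
        genome = self._genome_with_gene(120, "+")
        feat = genome.features[0]
        genome.features[0] = Feature("g1", "ctg", feat.start, feat.end, "-")
        (a,) = assign_regulon(scan_consensus(genome), genome)
        assert not a.assigned

    def test_mirrored_genome_yields_mirrored_assignments(self):
        genome = self._genome_with_gene(77, "+")
        L = len(genome.contigs["ctg"])
        feat = genome.features[0]
        mirrored = make_genome(
            reverse_complement(genome.contigs["ctg"]),
            [Feature("g1", "ctg", L - feat.end, L - feat.start, "-")],
        )
        (a,) = assign_regulon(scan_consensus(genome), genome)
        (b,) = assign_regulon(scan_consensus(mirrored), mirrored)
        assert (a.gene_id, a.distance) == (b.gene_id, b.distance)
        assert b.hit.strand == "-"

    def test_never_assigns_across_contigs(self):
        motif = "TGGCAGATTACTTGCA"[:16]
        cds = "ATG" + "GCA" * 30 + "TAA"
        genome = AnnotatedGenome(
            contigs={"c1": "C" * 40 + motif + "C" * 44, "c2": cds + "C" * 50},
            features=[Feature("g1", "c2", 0, len(cds), "+")],
        )
        (a,) = assign_regulon(scan_consensus(genome), genome)
        assert not a.assigned

    def test_planted_units_match_truth(self, sim_genome, sim_config):
        genome, truth = sim_genome
        hits = scan_consensus(genome)
        assignments = assign_regulon(hits, genome)
        by_locus = {(u.contig_id, u.motif_start, u.strand): u for u in truth.units}
        assert len(assignments) == len(truth.units)
        for a in assignments:
            u = by_locus[(a.hit.contig_id, a.hit.start, a.hit.strand)]
            assert a.gene_id == u.lead_gene
            assert a.distance == u.distance
            assert a.transcriptional_unit == u.unit_genes
            flag_ebp_vicinity(a, genome, span=sim_config.ebp_span)
            assert (a.ebp_nearby, a.ebp_gene_id) == (u.ebp, u.ebp_gene)


class TestOperons:
    def _layout(self, specs):
        # specs: list of (start, length, strand)
        feats = [
            Feature(f"g{i + 1}", "ctg", s, s + ln, std)
            for i, (s, ln, std) in enumerate(specs)
        ]
        contig = "A" * (max(s + ln for s, ln, _ in specs) + 10)
        return make_genome(contig, feats)

    def test_three_codirectional_genes_small_gaps(self):
        genome = self._layout([(0, 90, "+"), (110, 90, "+"), (220, 90, "+")])
        assert extend_operon(genome, "g1", max_gap=50) == ["g1", "g2", "g3"]

    def test_opposite_strand_breaks_unit(self):
        genome = self._layout([(0, 90, "+"), (110, 90, "-")])
        assert extend_operon(genome, "g1", max_gap=50) == ["g1"]

    def test_minus_strand_extends_leftwards(self):
        genome = self._layout([(0, 90, "-"), (110, 90, "-"), (400, 90, "-")])
        assert extend_operon(genome, "g2", max_gap=50) == ["g2", "g1"]

    def test_random_layouts_vs_gap_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            cursor, specs = 0, []
            for _ in range(int(rng.integers(2, 8))):
                cursor += int(rng.integers(0, 120))
                ln = int(rng.integers(30, 150))
                specs.append((cursor, ln, "+" if rng.random() < 0.5 else "-"))
                cursor += ln
            genome = self._layout(specs)
            max_gap = int(rng.integers(10, 100))
            lead = int(rng.integers(0, len(specs)))
            got = extend_operon(genome, f"g{lead + 1}", max_gap=max_gap)
            # oracle: walk the explicit layout list in gene orientation
            expect = [f"g{lead + 1}"]
            strand = specs[lead][2]
            order = range(lead + 1, len(specs)) if strand == "+" else range(lead - 1, -1, -1)
            prev = lead
            for j in order:
                gap = (
                    specs[j][0] - (specs[prev][0] + specs[prev][1])
                    if strand == "+"
                    else specs[prev][0] - (specs[j][0] + specs[j][1])
                )
                if specs[j][2] != strand or gap > max_gap:
                    break
                expect.append(f"g{j + 1}")
                prev = j
            assert got == expect


class TestEbpFlag:
    def _assignment(self, genome):
        (a,) = assign_regulon(scan_consensus(genome), genome)
        assert a.assigned
        return a

    def _base(self, ebp_product, ebp_gap):
        motif = "TGGCAGATTACTTGCA"[:16]
        cds = "ATG" + "GCA" * 40 + "TAA"
        ebp = "ATG" + "TTT" * 60 + "TAA"
        seq = (
            "C" * 100 + motif + "C" * 50 + cds + "C" * ebp_gap + ebp + "C" * 50
        )
        feats = [
            Feature("g1", "ctg", 166, 166 + len(cds), "+"),
            Feature(
                "ebp1",
                "ctg",
                166 + len(cds) + ebp_gap,
                166 + len(cds) + ebp_gap + len(ebp),
                "+",
                product=ebp_product,
            ),
        ]
        return make_genome(seq, feats)

    def test_adjacent_ebp_gene_flags_true(self):
        genome = self._base("sigma-54 dependent transcriptional regulator", 200)
        a = flag_ebp_vicinity(self._assignment(genome), genome, span=2000)
        assert a.ebp_nearby and a.ebp_gene_id == "ebp1"

    def test_no_ebp_within_span_flags_false(self):
        genome = self._base("sigma-54 dependent transcriptional regulator", 3000)
        a = flag_ebp_vicinity(self._assignment(genome), genome, span=2000)
        assert not a.ebp_nearby

    def test_non_ebp_product_not_flagged(self):
        genome = self._base("ABC transporter permease", 200)
        a = flag_ebp_vicinity(self._assignment(genome), genome, span=2000)
        assert not a.ebp_nearby

    def test_empty_keywords_rejected(self):
        genome = self._base("enhancer binding protein", 200)
        with pytest.raises(ValueError):
            flag_ebp_vicinity(self._assignment(genome), genome, keywords=[])


class TestScanStatistics:
    def test_closed_form_default_pattern(self):
        pattern = ConsensusPattern()
        assert pattern.match_probability == pytest.approx(1 / 524288)
        genome = make_genome("A" * 1_000_000)
        stats = scan_statistics([], genome, pattern)
        assert stats.expected_hits_random == pytest.approx(
            2 * (1_000_000 - 15) / 524288
        )
        assert stats.expected_hits_random == pytest.approx(3.81, abs=0.01)

    def test_all_n_pattern_every_window_matches(self):
        genome = make_genome("ACGT" * 300)
        pattern = ConsensusPattern("N" * 16)
        hits = scan_consensus(genome, pattern)
        stats = scan_statistics(hits, genome, pattern)
        L = 1200
        assert stats.expected_hits_random == 2 * (L - 15)
        assert stats.n_hits == 2 * (L - 15)
        assert stats.enrichment_ratio == pytest.approx(1.0)
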