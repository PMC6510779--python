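#!/usr/bin/env python
"""Optional validation: replay the regulon scan on a real assembly.

The genome-wide site counts reported for Clostridium beijerinckii (57
consensus sites, 35 of them within a few hundred bp upstream of a CDS)
require the actual DSM 6423 assembly, which is not redistributed here. If
you have the assembly locally (FASTA + GFF3, or a GenBank flat file), this
script reruns the scan and prints the counts under both conventions
(all sites vs upstream-assigned sites) so they can be compared with the
published ones.

Usage:
    python scripts/validate_real_genome.py --fasta genome.fna --gff genome.gff3
    python scripts/validate_real_genome.py --genbank genome.gbff
"""

from __future__ import annotations

import argparse

from sigma54_scope.genome import load_genome
from sigma54_scope.motifs import assign_regulon, scan_consensus, scan_statistics


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__.splitlines()[0])
    ap.add_argument("--fasta")
    ap.add_argument("--gff")
    ap.add_argument("--genbank")
    ap.add_argument("--window", type=int, default=500)
    args = ap.parse_args()
    if args.genbank:
        genome = load_genome(None, args.genbank, dialect="genbank")
    elif args.fasta and args.gff:
        genome = load_genome(args.fasta, args.gff, dialect="gff3")
    else:
        ap.error("provide --fasta and --gff, or --genbank")
    hits = scan_consensus(genome)
    stats = scan_statistics(hits, genome)
    assignments = assign_regulon(hits, genome, window=args.window)
    n_assigned = sum(a.assigned for a in assignments)
    plus_only = sum(1 for h in hits if h.strand == "+")
    print(f"genome: {genome.total_length:,} bp over {len(genome.contigs)} contig(s)")
    print(f"consensus sites (both strands, overlaps included): {len(hits)}")
    print(f"consensus sites (+ strand only): {plus_only}")
    print(f"sites <= {args.window} bp upstream of a CDS start: {n_assigned}")
    print(
        f"random expectation {stats.expected_hits_random:.1f} sites "
        f"(enrichment {stats.enrichment_ratio:.1f}x)"
    )


if __name__ == "__main__":
    main()
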