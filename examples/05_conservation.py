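"""Cross-strain regulon conservation with reciprocal-best-hit orthology.

Generates a query strain with four sigma-54 units plus two derived strains
in which each unit is kept with its motif, kept without it, or dropped
(the strain-specific-gene case), then recovers those statuses from
sequence alone.
"""

from sigma54_scope import (
    GenomeSimConfig,
    assign_regulon,
    compare_regulons,
    generate_genome_family,
    proteome,
    reciprocal_best_hits,
    scan_consensus,
)

config = GenomeSimConfig(seed=19, n_regulon_units=4, n_genes=12)
statuses = [
    ["conserved-with-motif", "conserved-gene-only", "absent", "conserved-with-motif"],
    ["absent", "conserved-with-motif", "conserved-gene-only", "conserved-gene-only"],
]
genomes, truths, family = generate_genome_family(config, statuses)

query = genomes[0]
regulons = [assign_regulon(scan_consensus(g), g) for g in genomes]
prot_query = proteome(query)

for g, reg in zip(genomes[1:], regulons[1:]):
    orthologs = reciprocal_best_hits(prot_query, proteome(g))
    report = compare_regulons(regulons[0], reg, orthologs, query.source_label, g.source_label)
    print(f"{query.source_label} vs {g.source_label}: "
          f"{len(orthologs.pairs)} ortholog pairs, statuses {report.counts()}")
    for lead, status in report.statuses.items():
        planted = family.conservation[lead][g.source_label]
        mark = "ok" if status == planted else "MISMATCH"
        print(f"  unit {lead}: {status:22s} (planted: {planted}, {mark})")
# "absent" units model genes private to one strain — present in the query
# regulon but without any ortholog in the target, like a strain-specific
# secondary alcohol dehydrogenase.
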