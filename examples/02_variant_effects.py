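"""Annotate point mutations into a resequencing-style mutation table.

Plants fifteen substitutions of known consequence (ten missense, one
nonsense, two synonymous, two intergenic — the composition of a typical
mutant-strain table) in a synthetic genome and annotates them back.
"""

from sigma54_scope import GenomeSimConfig, annotate_table, generate_genome, generate_variants

genome, _ = generate_genome(GenomeSimConfig(seed=42))
variants, truth = generate_variants(
    genome,
    {"Substitution": 10, "Truncation": 1, "None": 2, "Intergenic": 2},
    seed=23,
)

table = annotate_table(genome, variants)
print(table.to_string(index=False))
# columns mirror a published mutation table: locus tag, product, base change,
# genome and CDS coordinates, amino-acid change and effect class. A
# truncation row renders its new stop codon as "X" (e.g. "Q -> X").
print("\nclass counts:", dict(table["protein_effect"].value_counts()))
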