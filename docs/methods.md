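# Methods

## Scope and model

The package treats a bacterial chromosome as a set of contigs with
strand-aware gene/CDS intervals. Internally all coordinates are 0-based
half-open; every file boundary (FASTA, GFF3, GenBank, VCF, report TSVs) is
1-based inclusive, matching GFF3 and published mutation tables. Translation
uses the bacterial code (table 11); stop codons are rendered with the `X`
sentinel used by nonsense rows in mutation tables (`Q -> X`). Start codons
receive no special handling in translation — effect classification never
needs them.

## Promoter scanning and regulon assignment

σ⁵⁴ recognizes a bipartite −24/−12 element; the scan uses the consensus
`TGGCANNNNNNTTGCW` with **no mismatches**, i.e. a window matches iff every
base lies in the IUPAC set of the corresponding position. Matching is
implemented as an overlapping regex over each contig and its reverse
complement; minus-strand hits are reported in forward coordinates. Ambiguity
codes in the *genome* (e.g. `N`) never match, by design: a degenerate
genome base is not evidence of a site.

Assignment is **strand-matched**: the element is directional and the
consensus non-palindromic, so a site only drives a gene read in the same
orientation. The distance runs from the motif's 3′ end (promoter-proximal
edge in gene orientation) to the CDS start, inclusive window **[0, 500] bp**.
The nearest start wins; other in-window candidates are kept as alternatives;
sites overlapping a CDS are flagged but not excluded. Assigned genes are
extended into transcriptional units by the common prokaryotic heuristic:
co-directional consecutive CDS with intergenic gaps ≤ `max_gap` (default
50 bp, configurable); an opposite-strand gene breaks the run.

EBP vicinity is a keyword match on product annotations ("sigma-54
dependent", "enhancer", "PAS", "AAA", case-insensitive) within `span` bp of
the unit's genomic extent (unit members excluded). The library default is
5,000 bp — EBPs commonly act from several hundred bp up to a few kb away;
the synthetic generator uses 1,500 bp so that planted EBP genes are
unambiguously attributable to a single unit within a compact genome.

`scan_statistics` gives the i.i.d. equal-frequency background expectation
`2 · Σ_contigs (L − k + 1) · Π_positions |allowed|/4`; for the default
16-mer the per-window per-strand probability is `(1/4)^9 · (1/2) =
1/524288`, i.e. ≈ 3.81 expected sites per Mb on both strands.

## Conservation

Orthology is reduced to reciprocal best hits over translated CDS sets:
Smith–Waterman local alignment, BLOSUM62, gap open 11 / extend 1, minimum
score 50 (all configurable), ties broken by longer alignment then
lexicographic id. This is a deliberate desk-scale simplification of the
web-based synteny comparison a practitioner might use; an externally
supplied ortholog table (TSV) can override it. A query unit is matched by
single linkage through its member genes; it is *conserved-with-motif* when
some member's ortholog belongs to a motif-assigned unit in the target,
*conserved-gene-only* when orthologs exist outside the target regulon,
*absent* when no member has an ortholog. The three statuses partition every
query regulon.

## Variant effects

Only single-nucleotide substitutions are supported (indels are rejected
with a clear message); the observed genome base must equal the stated
reference base — a mismatch is a hard error carrying the observed base,
since it signals an assembly or coordinate mix-up rather than a biological
finding. For minus-strand genes, alleles are complemented onto the coding
strand before codon substitution. Classification: synonymous → *None*;
new stop → *Truncation*; changed residue → *Substitution* (stop-loss is a
flagged Substitution, as mutation tables have no precedent row for it);
outside every CDS → *Intergenic*. A position inside overlapping CDS yields
one row per feature. Codons containing ambiguity codes classify as
*Ambiguous* rather than guessing.

## Editing arithmetic

Primer binding is exact-match, which makes band-size prediction pure
arithmetic: amplicon length runs from the forward primer's 5′ end to the
reverse primer's 5′ end inclusive, and an internal deletion shrinks the
band by exactly the deleted length. Protospacer enumeration assumes SpCas9
(NGG PAM) with a blunt cut 3 bp 5′ of the PAM (between protospacer
positions 17 and 18); a protospacer is reported when its cut boundary falls
strictly inside the target interval. `residual_orf` splices the deletion
out of the CDS, translates from the original start and counts residues
before the first stop, excluding the stop itself; removing any base of the
start codon is reported as "no ORF".

## qPCR quantification

The efficiency-corrected ΔΔCq (Pfaffl) form is the default, honouring
per-amplicon reaction efficiencies; a plain-ΔΔCq mode (all E = 2) is a
flag. E is fold amplification per cycle in [1, 2] (2 = 100% efficiency);
percent inputs are auto-converted with a warning and values outside
[1.5, 2.1] are warned about. Standard-curve slopes convert via
`E = 10^(−1/slope)`. Replicates are aggregated by the arithmetic mean of Cq
before the ratio (the usual choice for duplicate wells); dispersion is
propagated as a worst-case ratio interval from the replicate Cq
half-ranges. The calibrator's own ratio is exactly 1 by construction, and
adding a constant to all of a sample's Cq values (equal E) leaves ratios
unchanged.

## Synthetic data: what it emulates, what it does not

The generator lays out gene "blocks" — optionally a consensus instance
(N/W positions randomized), an upstream gap of 0–500 bp, a lead gene,
0–2 co-directional operon members with 5–40 bp gaps, and for about half the
units an EBP-annotated gene 150–400 bp downstream — separated by
inter-block gaps larger than the EBP span, so every planted fact has an
unambiguous truth value. Genes are ATG + random sense codons + stop.
Background is i.i.d. (uniform by default; a low-GC ≈30% Clostridium-like
mode exists because hit-rate statistics depend on composition). When
`motif_free_background` is set, spontaneous consensus matches are removed
by rejection resampling: background windows are redrawn; matches overlapping
a gene redraw only the few interior codons under the window (start/stop
preserved, so proteins change by at most a handful of residues and ortholog
identity survives); matches overlapping a planted site re-randomize its
degenerate positions. Truth tables record final sequences after this scrub.
Default scale is a 100 kb contig with 30 genes and 5 units — a deliberately
scaled-down chromosome chosen so the full pipeline runs in seconds.

What passing on this data does **not** show: real σ⁵⁴ sites diverge from
the consensus (no-mismatch scanning on real genomes undercounts), real
operon structure does not reduce to a 50 bp gap rule, product-text keyword
matching inherits annotation quality, and RBH is cruder than synteny-aware
orthology. The generator also omits repeated sequence, mobile elements and
composition gradients, all of which produce spurious or missed hits on real
chromosomes.

qPCR simulation inverts the Pfaffl relation exactly (per-sample loading
shifts of ±0.5 cycles on the reference, per-target base Cq in 22–26) and
adds independent Gaussian noise per replicate well. Default conditions —
true fold changes of order 1–10, E in 1.88–2.0, sd 0.15 cycles, duplicate
wells — mirror a typical complementation experiment where measured fold
changes of ≈2.5–10 are the effects of interest. Real data additionally have
pipetting outliers, inhibition and between-run drift that the model omits.

## Numerical and design choices

- Overlapping motif matches are all reported; counts on both strands are
  the default convention (and the report distinguishes both conventions),
  since published "site" counts rarely state theirs.
- The 500 bp Methods-style window is taken as operative where narrative
  text says "a few hundred base pairs".
- Variant tables report raw row counts; reconciling a narrative SNP count
  with table rows is left to the user.
- Codon arithmetic supports codon 366 for a CDS position of 1,097
  (`⌊1096/3⌋+1`); where two residue numberings circulate for the same
  mutation, the one consistent with the stated CDS position is used.
- Deterministic ordering everywhere: hits by (contig, start, strand),
  variants by genome position, RBH ties by alignment length then id.
- All generators run from `numpy.random.default_rng(seed)` with integer
  state only; identical seeds give byte-identical outputs.
- Acceptance-style recovery runs use 20-unit genomes on 130 kb contigs
  (3 seeds in the script, 10 in the test suite) and 1,000 planted variants
  — sizes chosen so the whole suite stays interactive while estimates like
  the Monte-Carlo hit rate retain enough events to be meaningful.

## Known limitations

No mismatch tolerance or PWM scoring (exact consensus only); no de novo
motif discovery; no −12/−24 spacer optimization. Variant support is
SNV-only. The PCR model ignores melting temperature and near-match priming.
Protospacer enumeration does no off-target or efficiency scoring. The CLI
is a thin convenience layer; the library API is the primary interface.
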