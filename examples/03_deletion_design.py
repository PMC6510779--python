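"""CRISPR deletion arithmetic: band sizes, protospacers, residual ORF.

Builds a locus with a 1,406 bp colony-PCR amplicon, deletes a 736 bp
fragment inside it (the sigL-deletion design), and checks what a gel and
the truncated protein would show.
"""

import numpy as np

from sigma54_scope import (
    AnnotatedGenome,
    DeletionDesign,
    PrimerPair,
    apply_deletion,
    enumerate_protospacers,
    in_silico_pcr,
    residual_orf,
    translate_cds,
)
from sigma54_scope.genome import reverse_complement

rng = np.random.default_rng(1)
bases = np.array(list("ACGT"))
rand = lambda n: "".join(bases[rng.integers(0, 4, n)])

fwd, rev = rand(21), rand(21)
seq = rand(1000) + fwd + rand(1406 - 42) + reverse_complement(rev) + rand(1000)
genome = AnnotatedGenome(contigs={"locus": seq})
primers = PrimerPair(fwd, rev, "RH129", "RH130")

wt, _ = in_silico_pcr(genome, primers)
cut = 1000 + 21 + 400
edited = apply_deletion(genome, DeletionDesign("locus", cut, cut + 736))
dl, _ = in_silico_pcr(edited, primers)
print(f"wild-type band {wt} bp, deletion band {dl} bp (difference {wt - dl} bp)")
# exact-match primer binding makes band prediction pure arithmetic:
# the edited band is smaller by exactly the deleted length

spacers = enumerate_protospacers(genome, "locus", (cut, cut + 736))
print(f"{len(spacers)} SpCas9 protospacers cut inside the deleted interval "
      f"({sum(s.strand == '+' for s in spacers)} on +)")
# each is a 20-mer next to an NGG PAM whose blunt cut (3 bp from the PAM)
# falls inside the fragment to be removed

codons = ["GCA"] * 464
codons[0], codons[463] = "ATG", "TAA"
cds = list("".join(codons))
cds[39 + 736 : 39 + 739] = list("TAA")
cds = "".join(cds)
full = len(translate_cds(cds)) - 1
print(f"ORF: {full} residues intact, "
      f"{residual_orf(cds, (39, 39 + 736))} residues after the 736 bp deletion")
# the out-of-frame deletion runs into a stop at codon 14: a 13-residue stub
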