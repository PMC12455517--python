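"""Canonical oligos used throughout the pipeline.

The universal V3-V4 primer pair (341F/805R), the alternate 338F forward
primer, the recurrent 5' off-target consensus motifs (full and reduced
degenerate forms), the three chromosome-specific 3' motifs, and the
24-mer blocking oligonucleotide derived from the 5' consensus.
"""

from .seqcore import NucSequence, Oligo, OligoRole, ThreePrimeMod

#: 341F, forward primer targeting the 16S V3 region.
PRIMER_341F = Oligo("341F", NucSequence("CCTACGGGNGGCWGCAG"), OligoRole.forward_primer)

#: 805R, reverse primer targeting the 16S V4 region.
PRIMER_805R = Oligo("805R", NucSequence("GACTACNVGGGTWTCTAATCC"), OligoRole.reverse_primer)

#: 338F, alternate forward primer used by some studies.
PRIMER_338F = Oligo("338F", NucSequence("ACTCCTACGGGAGGCAGCAG"), OligoRole.forward_primer)

#: Full degenerate 5' consensus of recurrent host off-targets (33 columns,
#: including low-frequency degeneracies and a low-coverage trailing column).
FIVE_PRIME_CONSENSUS_FULL = NucSequence("TGATAAACCTTTMGCAATMMACSAAAGTTTAAV")

#: Reduced 5' consensus: low-frequency degeneracies collapsed, trailing
#: low-coverage column trimmed (32 nt; only the balanced S retained).
FIVE_PRIME_CONSENSUS_REDUCED = NucSequence("TGATAAACCTTTAGCAATAAACSAAAGTTTAA")

#: Chromosome-specific 29-nt 3' motifs of the three recurrent off-target loci.
THREE_PRIME_MOTIFS = {
    "chr5": NucSequence("CAGTTTGGGTCTTAGCTATTGTGTGTTCA"),
    "chr11": NucSequence("CAGTTTGGGTCTTAGTTATTCTGTGTTCA"),
    "chr17": NucSequence("CAGTTTGAATCTTCGCTATTGTGTATTCA"),
}

#: 24-mer blocking oligo: the 5' consensus prefix with a 3' C3 spacer, so it
#: anneals immediately downstream of the forward-primer-like region but
#: cannot be extended.
INHIBITOR_24MER = Oligo(
    "offtarget-inhibitor",
    NucSequence("TGATAAACCTTTAGCAATAAACSA"),
    OligoRole.inhibitor,
    ThreePrimeMod.C3_spacer,
)
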