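# Methods

## The problem being modeled

"Universal" 16S rRNA V3–V4 primers (341F `CCTACGGGNGGCWGCAG`, 805R
`GACTACNVGGGTWTCTAATCC`) can anneal to host (human) DNA at sites that are
imperfect copies of the primer but perfect over its 3'-terminal bases.
When two such sites sit on opposite strands in convergent orientation
within amplifiable distance, PCR produces a host "off-target" amplicon
that is sequenced alongside the genuine 16S product.  In samples with a
high host-to-bacteria DNA ratio (e.g. intestinal biopsies) these
off-targets can consume a large share of the sequencing depth and bias
every downstream community summary.

The package implements the forensic chain: find the mis-priming sites,
pair them into predicted products, classify sequenced features into host
vs microbial, derive the recurrent off-target consensus motif, design a
blocking oligonucleotide against it, and quantify the community-analysis
bias of leaving host reads in.

## Mis-priming model

A priming site is an ungapped placement of the primer where

* the `anchor_len` 3'-terminal bases match perfectly (IUPAC base-set
  intersection; `N` in the genome matches nothing), and
* at most `max_mismatches` positions mismatch outside the anchor.

Defaults are `anchor_len = 5`, `max_mismatches = 4`: the recurrent human
landings show perfect 3' ends with 2–4 internal/5' mismatches, so the
window is set just wide of that regime.  The model is deliberately
combinatorial rather than thermodynamic — a ΔG-based annealing
probability would need buffer and temperature parameters the use case
does not constrain — and it is exactly checkable against a brute-force
matcher, which the test suite does on seeded random genomes.

Amplicons are all convergent opposite-strand site pairs (plus-strand site
leftmost, 3' ends facing) with product length in `[min_len, max_len]`
(default 100–600 bp, covering both the ~250 bp off-target and the
~460 bp V3–V4 product).  Coordinates are 0-based half-open internally;
reports add a 1-based column, and BED output stays 0-based per the BED
standard.

## Consensus calling

Off-target reads from one locus share an exact primer-defined start, so
a gapless end-anchored alignment (truncation to a fixed window: 32 nt at
the 5' end, 29 nt at the 3' end) replaces a general MSA; gaps have
nothing to align.  A position frequency matrix is built with ambiguous
residues distributed fractionally over their base sets.  Two consensus
strings are derived per column:

* **full**: every base with frequency ≥ `include_freq` (default 0.25)
  enters the IUPAC code;
* **reduced**: bases below `drop_freq` (default 0.10) are discarded, so a
  column whose minor bases are all low-frequency collapses to its
  majority base; trailing columns observed in fewer than `min_coverage`
  (default 0.50) of the sequences are trimmed.

These thresholds reproduce the intended distinction between a fully
degenerate motif and its cleaned form in which only balanced
degeneracies (an S column split roughly 50/50 between C and G) survive.
`locate_motif` searches a consensus on a reference (both strands,
IUPAC-aware, ≤ `max_mismatch` mismatches) and reports 1-based positions.

## Oligo physics

Melting temperatures are nearest-neighbor (unified parameter set, via
Biopython's `Tm_NN`) with the entropic monovalent-salt correction, at
50 mM Na+ and 0.25 µM oligo.  Degenerate oligos report the arithmetic
mean over their concrete expansions (min/max also available).  The test
suite checks the implementation against an independently hand-summed
nearest-neighbor computation with published ΔH/ΔS values.

The hairpin scan is exhaustive over window pairs: a stem of length ≥
`min_stem` (default 4) whose windows are IUPAC-aware reverse complements,
separated by a loop ≥ `min_loop` (default 3).  A reported stem must
additionally contain at least one G·C-capable pair: a 4-bp all-A/T stem
does not hold together at annealing temperatures, and without this
stability criterion the known hairpin-free 24-mer blocking oligo would be
flagged on a spurious TTTA/TAAA stem.

## Blocking-oligo design

The candidate inhibitor is a 5'-anchored prefix of the reduced 5'
consensus — by construction it anneals immediately downstream of the
forward-primer-like genomic region — annotated with a 3' C3 spacer so it
can never be extended.  With `explicit_length` the prefix is taken
verbatim (length 24 reproduces `TGATAAACCTTTAGCAATAAACSA`); otherwise the
shortest length in `length_range` (default 20–26) whose Tm falls within
`tm_window` (default ±5 °C) of the mean primer Tm is chosen.  A design is
accepted iff it meets the Tm window, forms no hairpin, and has no
priming-competent site (anchor-perfect, ≤ 3 mismatches) on the supplied
microbial reference set.

## Community bias

* **Filtering** operates at genus level: a genus is kept iff its maximum
  per-sample relative abundance is ≥ 0.01% and it occurs in ≥ 1% of the
  samples; organelle (mitochondria/chloroplast) and phylum-unassigned
  features may be dropped first.  Every removal is logged with its
  reason.  The filter is idempotent because removals only raise the
  relative abundance of what remains.
* **With/without comparison**: relative abundances are computed twice,
  differing only in whether host features enter the per-sample
  denominators (host reads pooled into one pseudo-taxon so each mode
  sums to 1).  Removing host reads can only raise microbial abundances.
* **Rarefaction** is analytic rather than a single random subsample:
  E[S(n)] = Σ_g (1 − C(N−N_g, n)/C(N, n)), evaluated every `step`
  (default 100) reads.  A sample is saturated when the final one-step
  slope is below `1e-4` genera/read; the one-step window is a choice
  (configurable) since a fitted tail would be equally defensible.
  Samples with fewer than 2·step reads are reported unevaluable.
* **Ordination** is classical PCoA (via scikit-bio) on Hellinger
  distances — Euclidean distance on square-root transformed relative
  abundances, maximum √2 for taxon-disjoint samples.  Hellinger
  distances are Euclidean-embeddable, so materially negative eigenvalues
  trigger a warning; coordinates use positive-eigenvalue axes only and
  proportions explained are over the positive-eigenvalue sum.

Differential abundance is intentionally not implemented; the bias stage
emits the two filtered tables (with and without off-targets) ready for
external tools.

## Synthetic study system

The generator emulates the study conditions with known truth:

* **Host genome**: 3 chromosomes × 50 kb of uniform-random background,
  screened at generation (regenerated up to 100× until the scanner finds
  only the planted sites).  Each planted locus is, on the forward
  strand: a 341F-like landing with mismatches planted at 3'-offsets
  (7, 12), the 32-nt 5' consensus, a spacer, the reverse-complemented
  29-nt 3' motif, and a reverse-complemented 805R-like landing with
  mismatches at offsets (6, 11) — total product 248 bp, the outer span
  implied by the printed chr17 coordinates.  Degenerate motif positions
  are resolved cyclically across loci so the S column stays balanced.
* **Mock community**: 20 templates = concrete 341F expansion + 427-nt
  random insert + reverse-complemented 805R expansion (~465 bp product),
  Dirichlet(1) abundances, screened to contain neither the consensus nor
  an inhibitor-primable site.  Kitome contaminants are identical in
  construction but at very low copy number (5 vs 1e3 genuine templates).
* **PCR**: deterministic exponential weights
  `W_t = T_t (1 + e_t)^cycles` with
  `e_t = e0 ρ^{m_t} (1 − binding · I_t)`, then multinomial read draws
  and per-base substitution errors (constant Phred 35 qualities).
  Defaults: `e0 = 0.95`, `ρ = 0.6`, `error_rate = 0.005`, 25 cycles
  (35 for the contaminant-enhancing preset), depth 50,000.
  `I_t = 1` when the blocking oligo anchor-matches immediately
  downstream of the template's forward landing, verified by actually
  scanning the template.
* **Copy numbers**: 1e8 host genome equivalents per locus vs 1e3
  microbial 16S templates — the host-dominated biopsy regime.  With the
  4 planted mismatches this yields a default off-target read fraction of
  ~23%, inside the observed cross-cohort range (<0.1% to ~30%); the
  extremes of that range are reachable by scaling host copies, which the
  tests assert.

What the simulator does *not* capture: per-cycle stochastic branching
(early-cycle qPCR variability between technical replicates), chimeras,
indels, quality profiles, and paired-end structure.  Passing tests
therefore demonstrate correctness of the analysis chain under separable,
well-specified contamination — not robustness to every artifact of real
sequencing runs.

## Problem sizes and numerics

The test suite runs the full chain on 3 × 50 kb genomes at depth 20,000
(50,000 in library defaults), Monte-Carlo checks at 100 seeds for
consensus recovery and 10,000 replicates for rarefaction, and brute-force
oracle comparisons on 100 random genomes of ≤ 2 kb — sizes at which the
oracles are exact and the suite completes in well under a minute.
Tie-breaks are deterministic throughout: scanner output is sorted by
(chrom, start, strand); the aligner prefers higher (identity,
aligned length), then lexicographic chromosome, lower start, plus
strand; consensus majority ties resolve alphabetically; cluster modes
prefer the lower coordinate at equal weight.

## Known limitations

* The aligner is k-mer-seeded and ungapped — adequate for desk-scale
  references and exactly testable, but not a replacement for Bowtie2 or
  BLAST on full genomes; SAM ingestion covers that route.
* Mis-priming is combinatorial, not thermodynamic; a site's efficiency
  penalty in the PCR model (ρ per mismatch) is a coarse stand-in.
* The blocking-oligo validation does not model heterodimers or
  divalent-cation effects.
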