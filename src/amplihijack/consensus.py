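"""IUPAC consensus motifs from off-target sequence sets.

Off-target reads produced by a shared mis-priming locus begin at the
same template position once the primer has been trimmed, so a gapless
end-anchored alignment suffices: sequences are truncated to a fixed
window from the chosen end and stacked into columns.  A position
frequency matrix (PFM) over the columns yields two IUPAC consensus
strings:

* ``iupac_full`` — every base whose column frequency reaches
  ``include_freq`` enters the degenerate code;
* ``iupac_reduced`` — degeneracies whose minor bases all fall below
  ``drop_freq`` are collapsed to the majority base, and trailing columns
  observed in fewer than ``min_coverage`` of the sequences are trimmed.

``locate_motif`` then finds a consensus (degeneracies included) on a
reference, the in-package analogue of searching the motif with BLASTn.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqcore import IUPAC_SETS, NucSequence, reverse_complement

__all__ = [
    "ConsensusMotif",
    "anchor_align",
    "build_pfm",
    "call_iupac_consensus",
    "locate_motif",
]

_BASES = "ACGT"
_SET_TO_CODE = {frozenset(v): k for k, v in IUPAC_SETS.items()}


@dataclass
class ConsensusMotif:
    """Position frequency matrix plus derived IUPAC consensus strings.

    ``pfm`` is a (4, L) array of per-column base counts ordered A,C,G,T;
    ambiguous input residues contribute fractionally to each base of
    their expansion set, so column sums never exceed ``n_seqs``.
    """

    pfm: np.ndarray
    n_seqs: int
    iupac_full: NucSequence | None = None
    iupac_reduced: NucSequence | None = None
    include_freq: float | None = None
    drop_freq: float | None = None
    min_coverage: float | None = None

    @property
    def length(self) -> int:
        return self.pfm.shape[1]

    def column_frequencies(self) -> np.ndarray:
        """(4, L) per-column base frequencies (columns sum to 1)."""
        sums = self.pfm.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(sums > 0, self.pfm / sums, 0.0)


def anchor_align(
    seqs: list[NucSequence | str],
    end: str = "five_prime",
    window: int = 32,
) -> list[NucSequence]:
    """Gapless end-anchored alignment: truncate each sequence to ``window``
    bases from the chosen end.

    For ``three_prime`` the sequences are reverse-complemented first, so
    the returned block reads 5'->3' of the bottom-strand motif.  Primer
    prefixes must already be trimmed by the caller.
    """
    if end not in ("five_prime", "three_prime"):
        raise ValueError(f"end must be 'five_prime' or 'three_prime', got {end!r}")
    block: list[NucSequence] = []
    for i, s in enumerate(seqs):
        s = s if isinstance(s, NucSequence) else NucSequence(s)
        if len(s) < window:
            raise ValueError(
                f"sequence {i} (length {len(s)}) is shorter than the "
                f"{window}-base window"
            )
        if end == "three_prime":
            s = reverse_complement(s)
        block.append(NucSequence(str(s)[:window]))
    return block


def build_pfm(block: list[NucSequence | str]) -> ConsensusMotif:
    """Count bases per column of an equal-length block.

    Ambiguous residues distribute fractionally across their expansion set
    (an S adds 0.5 to C and 0.5 to G).
    """
    if not block:
        raise ValueError("empty block")
    L = len(block[0])
    if any(len(s) != L for s in block):
        raise ValueError("ragged block: sequences differ in length")
    pfm = np.zeros((4, L), dtype=float)
    for s in block:
        for j, c in enumerate(str(s).upper()):
            bases = IUPAC_SETS[c]
            w = 1.0 / len(bases)
            for b in bases:
                pfm[_BASES.index(b), j] += w
    return ConsensusMotif(pfm=pfm, n_seqs=len(block))


def _column_code(freqs: np.ndarray, threshold: float) -> str:
    """IUPAC code of the bases whose frequency reaches ``threshold``;
    falls back to the (alphabetically first) majority base if none do."""
    kept = frozenset(_BASES[i] for i in range(4) if freqs[i] >= threshold)
    if not kept:
        kept = frozenset({_BASES[int(np.argmax(freqs))]})
    return _SET_TO_CODE[kept]


def call_iupac_consensus(
    motif: ConsensusMotif,
    include_freq: float = 0.25,
    drop_freq: float = 0.10,
    min_coverage: float = 0.50,
) -> ConsensusMotif:
    """Derive the full and reduced IUPAC consensus strings from a PFM.

    Per column, bases with frequency >= ``include_freq`` form the full
    code.  The reduced form keeps only bases with frequency >=
    ``drop_freq``; a column whose minor bases all fall below ``drop_freq``
    therefore collapses to its majority base.  Trailing columns with
    fewer than ``min_coverage * n_seqs`` observations are trimmed from
    the reduced form.
    """
    if not (0 < include_freq <= 1):
        raise ValueError("include_freq must be in (0, 1]")
    freqs = motif.column_frequencies()
    full = "".join(_column_code(freqs[:, j], include_freq) for j in range(motif.length))

    reduced_cols = [
        _column_code(freqs[:, j], max(drop_freq, np.finfo(float).tiny))
        for j in range(motif.length)
    ]
    coverage = motif.pfm.sum(axis=0)
    cut = motif.length
    while cut > 0 and coverage[cut - 1] < min_coverage * motif.n_seqs:
        cut -= 1
    reduced = "".join(reduced_cols[:cut])

    return ConsensusMotif(
        pfm=motif.pfm,
        n_seqs=motif.n_seqs,
        iupac_full=NucSequence(full),
        iupac_reduced=NucSequence(reduced),
        include_freq=include_freq,
        drop_freq=drop_freq,
        min_coverage=min_coverage,
    )


def locate_motif(
    motif: NucSequence | str,
    reference: dict[str, str],
    max_mismatch: int = 0,
) -> list[tuple[str, int, str, int]]:
    """All IUPAC-aware ungapped occurrences of a motif on both strands.

    Returns (chrom, 1-based position of the leftmost matched base, strand,
    n_mismatches) tuples sorted by (chrom, position).  Reuses the
    mis-priming scanner with a zero-length anchor, i.e. a plain degenerate
    string search with up to ``max_mismatch`` mismatches anywhere.
    """
    from .mispriming import _encode_genome, _encode_primer, _scan_one_strand

    m = motif if isinstance(motif, NucSequence) else NucSequence(motif)
    if len(m) < 12:
        raise ValueError(f"motif of length {len(m)} is too short (minimum 12)")
    no_anchor = np.zeros(len(m), dtype=bool)
    fwd_bits = _encode_primer(m)
    rev_bits = _encode_primer(reverse_complement(m))
    hits: list[tuple[str, int, str, int]] = []
    for chrom in sorted(reference):
        gbits = _encode_genome(str(reference[chrom]))
        for strand, bits in (("+", fwd_bits), ("-", rev_bits)):
            starts, mm = _scan_one_strand(gbits, bits, no_anchor, max_mismatch)
            hits.extend((chrom, int(s) + 1, strand, len(cols))
                        for s, cols in zip(starts, mm))
    hits.sort(key=lambda h: (h[0], h[1], h[2]))
    return hits
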