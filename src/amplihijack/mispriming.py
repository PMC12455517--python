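"""Genome-wide mis-priming scan and off-target amplicon prediction.

Mis-priming — extension of a primer annealed to an imperfectly
complementary site — is strongly favored when the primer's 3'-terminal
bases pair perfectly, even if 5'/central bases mismatch.  The scanner
models exactly that geometry: a site is reported when the primer aligns
ungapped with a perfect IUPAC match over its 3'-terminal ``anchor_len``
bases and at most ``max_mismatches`` mismatches elsewhere.

Convergent pairs of such sites (opposite strands, 3' ends facing) within
a product-length window are the predicted off-target amplicons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqcore import BITS_LUT, IUPAC_BITS, NucSequence, Oligo, reverse_complement

__all__ = [
    "ScanParams",
    "PrimingSite",
    "PredictedAmplicon",
    "MisprimingAlignment",
    "scan_priming_sites",
    "predict_amplicons",
    "annotate_mispriming",
]

# Genome-side encoding: only concrete bases carry bits; N (and any other
# ambiguity in the reference) never matches a primer base.
_GENOME_LUT = np.zeros(256, dtype=np.uint8)
for _b in "ACGT":
    _GENOME_LUT[ord(_b)] = IUPAC_BITS[_b]
    _GENOME_LUT[ord(_b.lower())] = IUPAC_BITS[_b]


@dataclass(frozen=True)
class ScanParams:
    """Parameters of the 3'-anchored mismatch model.

    anchor_len
        Number of 3'-terminal primer bases that must match perfectly.
    max_mismatches
        Mismatches tolerated outside the anchor.
    allow_indels
        Reserved; gapped priming is not modeled.
    """

    anchor_len: int = 5
    max_mismatches: int = 4
    allow_indels: bool = False

    def __post_init__(self) -> None:
        if self.anchor_len <= 0:
            raise ValueError("anchor_len must be positive")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        if self.allow_indels:
            raise NotImplementedError("gapped priming is not modeled")


@dataclass(frozen=True, order=True)
class PrimingSite:
    """One primer-like landing locus on a genome.

    ``start`` is the 0-based leftmost genome coordinate of the landing
    (half-open interval ``[start, start + primer_len)``).  Mismatch
    offsets are distances from the primer's 3' end (0 = terminal base);
    because emitted sites always satisfy the anchor, every offset is
    >= the anchor length used for the scan.
    """

    chrom: str
    start: int
    strand: str
    primer_name: str
    primer_len: int
    mismatch_offsets: tuple[int, ...] = ()
    anchor_intact: bool = True

    @property
    def n_mismatches(self) -> int:
        return len(self.mismatch_offsets)

    @property
    def end(self) -> int:
        return self.start + self.primer_len

    @property
    def pos_1based(self) -> int:
        return self.start + 1


@dataclass(frozen=True)
class PredictedAmplicon:
    """A convergent pair of priming sites and the product they define."""

    fwd_site: PrimingSite
    rev_site: PrimingSite
    product_start: int
    product_end: int
    insert_seq: NucSequence

    @property
    def chrom(self) -> str:
        return self.fwd_site.chrom

    @property
    def product_len(self) -> int:
        return self.product_end - self.product_start


@dataclass(frozen=True)
class MisprimingAlignment:
    """Textual primer-vs-genome alignment for one priming site."""

    primer: str
    genome_window: str
    match_flags: tuple[bool, ...]

    @property
    def n_mismatches(self) -> int:
        return sum(not f for f in self.match_flags)

    def __str__(self) -> str:
        marks = "".join("|" if f else "*" for f in self.match_flags)
        return f"{self.primer}\n{marks}\n{self.genome_window}"


def _encode_genome(seq: str) -> np.ndarray:
    arr = np.frombuffer(str(seq).encode("ascii"), dtype=np.uint8)
    return _GENOME_LUT[arr]


def _encode_primer(seq: NucSequence) -> np.ndarray:
    arr = np.frombuffer(str(seq).encode("ascii"), dtype=np.uint8)
    return BITS_LUT[arr]


def _scan_one_strand(
    gbits: np.ndarray,
    pbits: np.ndarray,
    anchor_cols: np.ndarray,
    max_mismatches: int,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Return (starts, per-start mismatch column arrays) for one pattern.

    ``anchor_cols`` is a boolean mask over pattern columns that must match
    perfectly; mismatches are counted over the remaining columns.
    """
    L = len(pbits)
    n = len(gbits)
    if n < L:
        return np.empty(0, dtype=np.int64), []
    windows = np.lib.stride_tricks.sliding_window_view(gbits, L)
    match = (windows & pbits[np.newaxis, :]) != 0
    ok = match[:, anchor_cols].all(axis=1)
    n_mm = (~match[:, ~anchor_cols]).sum(axis=1)
    hits = np.flatnonzero(ok & (n_mm <= max_mismatches))
    mm_cols = [np.flatnonzero(~match[h]) for h in hits]
    return hits.astype(np.int64), mm_cols


def scan_priming_sites(
    genome: dict[str, str],
    primer: Oligo,
    params: ScanParams = ScanParams(),
) -> list[PrimingSite]:
    """Scan every position and strand of a genome for primer landings.

    Emits every site where the primer aligns ungapped with a perfect
    IUPAC match over its ``anchor_len`` 3'-terminal bases and at most
    ``max_mismatches`` mismatches elsewhere, sorted by
    (chrom, start, strand).  ``N`` in the genome never matches.
    """
    if not genome:
        raise ValueError("empty genome")
    pseq = primer.seq
    L = len(pseq)
    if L < params.anchor_len:
        raise ValueError(
            f"primer {primer.name} (length {L}) is shorter than the "
            f"anchor length {params.anchor_len}"
        )
    fwd_bits = _encode_primer(pseq)
    rev_bits = _encode_primer(reverse_complement(pseq))

    # + strand: pattern column k is primer index k, 3'-offset L-1-k.
    plus_anchor = np.zeros(L, dtype=bool)
    plus_anchor[L - params.anchor_len:] = True
    # - strand: the forward genome strand carries revcomp(primer); pattern
    # column k corresponds to primer 3'-offset k.
    minus_anchor = np.zeros(L, dtype=bool)
    minus_anchor[: params.anchor_len] = True

    sites: list[PrimingSite] = []
    for chrom in sorted(genome):
        gbits = _encode_genome(genome[chrom])
        starts, mm = _scan_one_strand(gbits, fwd_bits, plus_anchor, params.max_mismatches)
        for s, cols in zip(starts, mm):
            offsets = tuple(sorted(int(L - 1 - c) for c in cols))
            sites.append(PrimingSite(chrom, int(s), "+", primer.name, L, offsets))
        starts, mm = _scan_one_strand(gbits, rev_bits, minus_anchor, params.max_mismatches)
        for s, cols in zip(starts, mm):
            offsets = tuple(sorted(int(c) for c in cols))
            sites.append(PrimingSite(chrom, int(s), "-", primer.name, L, offsets))
    sites.sort(key=lambda x: (x.chrom, x.start, x.strand))
    return sites


def predict_amplicons(
    fwd_sites: list[PrimingSite],
    rev_sites: list[PrimingSite],
    min_len: int = 100,
    max_len: int = 600,
    genome: dict[str, str] | None = None,
) -> list[PredictedAmplicon]:
    """Pair convergent priming sites into predicted PCR products.

    A pair is convergent when the two sites sit on the same chromosome on
    opposite strands with the plus-strand site leftmost, so each primer's
    3' end points toward the other site.  The product spans both landings
    ([plus.start, minus.end)); only products whose length falls in
    [min_len, max_len] are emitted, sorted by (chrom, product_start).
    """
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    out: list[PredictedAmplicon] = []
    for f in fwd_sites:
        for r in rev_sites:
            if f.chrom != r.chrom or f.strand == r.strand:
                continue
            plus, minus = (f, r) if f.strand == "+" else (r, f)
            if plus.end > minus.start:
                continue  # not facing, or overlapping landings
            plen = minus.end - plus.start
            if not (min_len <= plen <= max_len):
                continue
            insert = ""
            if genome is not None:
                insert = str(genome[f.chrom])[plus.end: minus.start]
            out.append(
                PredictedAmplicon(
                    fwd_site=f,
                    rev_site=r,
                    product_start=plus.start,
                    product_end=minus.end,
                    insert_seq=NucSequence(insert),
                )
            )
    out.sort(key=lambda a: (a.chrom, a.product_start, a.product_end))
    return out


def annotate_mispriming(
    site: PrimingSite, primer: Oligo, genome: dict[str, str]
) -> MisprimingAlignment:
    """Render the primer-vs-genome alignment underlying a priming site.

    The genomic window is reverse-complemented for minus-strand sites so
    both rows read 5'->3' of the primer; the number of mismatch flags
    equals the site's mismatch count.
    """
    if site.primer_name != primer.name:
        raise ValueError(
            f"site was emitted for primer {site.primer_name!r}, "
            f"not {primer.name!r}"
        )
    if site.chrom not in genome:
        raise ValueError(f"chromosome {site.chrom!r} absent from genome")
    window = str(genome[site.chrom])[site.start: site.end].upper()
    if len(window) != site.primer_len:
        raise ValueError("site interval exceeds chromosome bounds")
    if site.strand == "-":
        window = str(reverse_complement(window))
    pseq = str(primer.seq)
    flags = tuple(
        bool(BITS_LUT[ord(p)] & _GENOME_LUT[ord(g)])
        for p, g in zip(pseq, window)
    )
    return MisprimingAlignment(primer=pseq, genome_window=window, match_flags=flags)
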