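"""IUPAC-aware sequence primitives.

Degenerate ("universal") 16S primers such as 341F (``CCTACGGGNGGCWGCAG``)
and 805R (``GACTACNVGGGTWTCTAATCC``) use IUPAC one-letter codes for base
sets.  Everything downstream of this module — mis-priming scans, consensus
calling, inhibitor design — treats a degenerate letter as the set of bases
it encodes, and two letters *match* when their sets intersect.

The module also provides the oligo-level physical checks needed to vet a
blocking oligonucleotide: nearest-neighbor melting temperature and an
exhaustive hairpin scan.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator

import numpy as np
from Bio.SeqUtils import MeltingTemp as _mt

__all__ = [
    "IUPAC_SETS",
    "IUPAC_BITS",
    "NucSequence",
    "Oligo",
    "OligoRole",
    "ThreePrimeMod",
    "HairpinReport",
    "iupac_match",
    "complement",
    "reverse_complement",
    "expand_degenerate",
    "degeneracy",
    "melting_temperature",
    "melting_temperature_range",
    "hairpin_scan",
]

#: IUPAC nucleotide codes mapped to the base sets they encode.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_BASE_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}

#: Bitmask encoding of each IUPAC code (A=1, C=2, G=4, T=8; unions for
#: degenerate codes).  Two codes match iff their masks intersect.
IUPAC_BITS: dict[str, int] = {
    code: sum(_BASE_BIT[b] for b in bases) for code, bases in IUPAC_SETS.items()
}

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

# 256-entry lookup: ASCII byte -> bitmask (0 for invalid characters).
BITS_LUT = np.zeros(256, dtype=np.uint8)
for _c, _v in IUPAC_BITS.items():
    BITS_LUT[ord(_c)] = _v
    BITS_LUT[ord(_c.lower())] = _v
BITS_LUT[ord("U")] = _BASE_BIT["T"]
BITS_LUT[ord("u")] = _BASE_BIT["T"]


class NucSequence(str):
    """An immutable nucleotide string over the IUPAC alphabet.

    Lowercase input is accepted and stored uppercase; ``U`` is normalized
    to ``T``.  Invalid characters are rejected at construction with the
    offending character and position named.
    """

    def __new__(cls, residues: str) -> "NucSequence":
        s = str(residues).upper().replace("U", "T")
        for i, ch in enumerate(s):
            if ch not in IUPAC_SETS:
                raise ValueError(
                    f"invalid IUPAC code {ch!r} at position {i} in sequence"
                )
        return super().__new__(cls, s)

    def reverse_complement(self) -> "NucSequence":
        return reverse_complement(self)

    @property
    def degeneracy(self) -> int:
        return degeneracy(self)


class OligoRole(str, Enum):
    forward_primer = "forward_primer"
    reverse_primer = "reverse_primer"
    inhibitor = "inhibitor"
    probe = "probe"


class ThreePrimeMod(str, Enum):
    none = "none"
    C3_spacer = "C3_spacer"


@dataclass(frozen=True)
class Oligo:
    """A named oligonucleotide with a role and optional 3' modification.

    An oligo carrying a 3' C3 spacer cannot be extended by a polymerase:
    it anneals but never primes, which is what makes it usable as a PCR
    clamp ("inhibitor").  Downstream code must never treat such an oligo
    as an extensible primer.
    """

    name: str
    seq: NucSequence
    role: OligoRole = OligoRole.probe
    three_prime_mod: ThreePrimeMod = ThreePrimeMod.none

    def __post_init__(self) -> None:
        if not isinstance(self.seq, NucSequence):
            object.__setattr__(self, "seq", NucSequence(self.seq))

    @property
    def is_extensible(self) -> bool:
        """True iff a polymerase can extend from this oligo's 3' end."""
        return self.three_prime_mod is not ThreePrimeMod.C3_spacer

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class HairpinReport:
    """Result of an exhaustive intramolecular hairpin scan."""

    has_hairpin: bool
    best_stem_len: int = 0
    best_loop_len: int = 0
    stem_positions: tuple[int, int] | None = None


def iupac_match(pattern_base: str, target_base: str) -> bool:
    """True iff the base sets of two IUPAC codes intersect.

    Symmetric; either side may be degenerate.
    """
    try:
        p = IUPAC_BITS[pattern_base.upper()]
    except KeyError:
        raise ValueError(f"invalid IUPAC code {pattern_base!r}") from None
    try:
        t = IUPAC_BITS[target_base.upper()]
    except KeyError:
        raise ValueError(f"invalid IUPAC code {target_base!r}") from None
    return bool(p & t)


def complement(base: str) -> str:
    try:
        return _COMPLEMENT[base.upper()]
    except KeyError:
        raise ValueError(f"invalid IUPAC code {base!r}") from None


def reverse_complement(seq: str) -> NucSequence:
    """IUPAC-aware reverse complement (an involution on all 15 codes)."""
    s = seq if isinstance(seq, NucSequence) else NucSequence(seq)
    return NucSequence("".join(_COMPLEMENT[c] for c in reversed(s)))


def degeneracy(seq: str) -> int:
    """Product of per-position base-set sizes."""
    s = seq if isinstance(seq, NucSequence) else NucSequence(seq)
    n = 1
    for c in s:
        n *= len(IUPAC_SETS[c])
    return n


def _expansions(seq: NucSequence) -> Iterator[str]:
    pools = [sorted(IUPAC_SETS[c]) for c in seq]
    for combo in itertools.product(*pools):
        yield "".join(combo)


def expand_degenerate(seq: str, limit: int = 256) -> list[NucSequence]:
    """All concrete A/C/G/T expansions of a degenerate sequence.

    Expansions are returned in lexicographic order; their count equals the
    product of per-position degeneracies.  Refuses (with the count named)
    when that product exceeds ``limit``.
    """
    s = seq if isinstance(seq, NucSequence) else NucSequence(seq)
    n = degeneracy(s)
    if n > limit:
        raise ValueError(
            f"degenerate expansion of {s!r} yields {n} sequences, "
            f"exceeding the limit of {limit}"
        )
    return [NucSequence(x) for x in _expansions(s)]


_MIN_TM_LENGTH = 8
_TM_EXPANSION_LIMIT = 64


def _tm_values(
    oligo: Oligo | str,
    monovalent_salt: float,
    oligo_conc: float,
) -> list[float]:
    seq = oligo.seq if isinstance(oligo, Oligo) else NucSequence(oligo)
    if len(seq) < _MIN_TM_LENGTH:
        raise ValueError(
            f"oligo of length {len(seq)} is too short for a nearest-neighbor "
            f"Tm (minimum {_MIN_TM_LENGTH})"
        )
    expansions = expand_degenerate(seq, limit=_TM_EXPANSION_LIMIT)
    # Tm_NN: unified NN parameters, monovalent-salt correction (SantaLucia),
    # concentrations in nM / mM.
    return [
        _mt.Tm_NN(
            e,
            Na=monovalent_salt * 1e3,
            dnac1=oligo_conc * 1e9,
            dnac2=0.0,
            selfcomp=False,
        )
        for e in expansions
    ]


def melting_temperature(
    oligo: Oligo | str,
    monovalent_salt: float = 0.05,
    oligo_conc: float = 0.25e-6,
) -> float:
    """Nearest-neighbor melting temperature in degrees Celsius.

    Parameters
    ----------
    oligo
        Oligo (or raw sequence) of length >= 8 with degeneracy <= 64.
    monovalent_salt
        Monovalent cation concentration in mol/L (default 50 mM).
    oligo_conc
        Oligo strand concentration in mol/L (default 0.25 uM).

    For degenerate oligos the arithmetic mean of the Tm over all concrete
    expansions is returned, which always lies between the expansion
    minimum and maximum.
    """
    return float(np.mean(_tm_values(oligo, monovalent_salt, oligo_conc)))


def melting_temperature_range(
    oligo: Oligo | str,
    monovalent_salt: float = 0.05,
    oligo_conc: float = 0.25e-6,
) -> tuple[float, float, float]:
    """(min, mean, max) Tm over the degenerate expansions of an oligo."""
    vals = _tm_values(oligo, monovalent_salt, oligo_conc)
    return (float(min(vals)), float(np.mean(vals)), float(max(vals)))


def _is_strong_pair(a: str, b: str) -> bool:
    """True when a stem base pair can be a G·C pair (both sides able to
    take G or C).  Used as a minimal stability criterion: an all-A/T stem
    of the minimum length does not hold together at annealing
    temperatures and is not reported as a hairpin."""
    gc = IUPAC_BITS["S"]
    return bool(IUPAC_BITS[a] & gc) and bool(IUPAC_BITS[b] & gc)


def hairpin_scan(
    oligo: Oligo | str,
    min_stem: int = 4,
    min_loop: int = 3,
    min_gc_pairs: int = 1,
) -> HairpinReport:
    """Exhaustively scan an oligo for intramolecular hairpins.

    A hairpin is a pair of windows (i earlier, j later) of equal length
    ``stem`` >= ``min_stem``, separated by a loop of >= ``min_loop`` bases,
    where the earlier window equals the IUPAC-aware reverse complement of
    the later one (each stem base pair matched by base-set intersection)
    and at least ``min_gc_pairs`` of the stem pairs are G·C-capable.
    The longest such stem is reported; among equal stems the leftmost,
    shortest-loop one.
    """
    if min_stem < 3 or min_loop < 3:
        raise ValueError("min_stem and min_loop must both be >= 3")
    seq = oligo.seq if isinstance(oligo, Oligo) else NucSequence(oligo)
    n = len(seq)
    best: tuple[int, int, int] | None = None  # (stem, i, j)
    for stem in range(min_stem, n // 2 + 1):
        for i in range(0, n - 2 * stem - min_loop + 1):
            for j in range(i + stem + min_loop, n - stem + 1):
                # stem pairing: seq[i+k] pairs with seq[j+stem-1-k]
                pairs = [(seq[i + k], seq[j + stem - 1 - k]) for k in range(stem)]
                if all(iupac_match(a, complement(b)) for a, b in pairs) and (
                    sum(_is_strong_pair(a, b) for a, b in pairs) >= min_gc_pairs
                ):
                    if best is None or stem > best[0]:
                        best = (stem, i, j)
    if best is None:
        return HairpinReport(has_hairpin=False)
    stem, i, j = best
    return HairpinReport(
        has_hairpin=True,
        best_stem_len=stem,
        best_loop_len=j - (i + stem),
        stem_positions=(i, j),
    )
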