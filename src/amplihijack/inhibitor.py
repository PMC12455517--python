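"""Blocking-oligonucleotide (PCR clamp) design against the off-target
consensus.

The mitigation strategy: an oligo identical to the 5' off-target
consensus — which begins immediately downstream of the forward-primer-like
genomic region — carrying a 3' C3 spacer.  It out-competes the forward
primer's extension product on the host template but cannot itself be
extended, suppressing off-target amplification without touching the 16S
primers.

A candidate is accepted when its melting temperature sits within a window
of the mean primer Tm, it forms no hairpin, and it cannot prime anywhere
on the supplied microbial reference set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .consensus import ConsensusMotif
from .mispriming import ScanParams, scan_priming_sites
from .seqcore import (
    HairpinReport,
    NucSequence,
    Oligo,
    OligoRole,
    ThreePrimeMod,
    hairpin_scan,
    melting_temperature,
)

__all__ = ["DesignParams", "InhibitorDesign", "design_inhibitor", "screen_cross_reactivity"]

_MIN_DESIGN_LEN = 15


@dataclass(frozen=True)
class DesignParams:
    """Constraints on the blocking-oligo search.

    length_range
        Candidate lengths tried (5'-anchored prefixes of the consensus).
    tm_window
        Maximum |Tm(candidate) - mean primer Tm| in degrees Celsius.
    anchor_len, max_mismatch
        Parameters of the cross-reactivity priming screen.
    explicit_length
        Skip the Tm-driven length search and take this prefix length.
    """

    length_range: tuple[int, int] = (20, 26)
    tm_window: float = 5.0
    anchor_len: int = 5
    max_mismatch: int = 3
    explicit_length: int | None = None

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if lo < _MIN_DESIGN_LEN:
            raise ValueError(f"minimum design length is {_MIN_DESIGN_LEN}, got {lo}")
        if self.explicit_length is not None and self.explicit_length < _MIN_DESIGN_LEN:
            raise ValueError(
                f"explicit_length {self.explicit_length} is below the "
                f"minimum design length {_MIN_DESIGN_LEN}"
            )


@dataclass(frozen=True)
class InhibitorDesign:
    """A candidate blocking oligo and its validation report."""

    oligo: Oligo
    tm: float
    delta_tm: float
    hairpin: HairpinReport
    cross_hits: tuple
    accepted: bool
    primer_tm_mean: float
    tm_window: float


def _mean_primer_tm(primers: list[Oligo]) -> float:
    if not primers:
        raise ValueError("at least one primer is required")
    return sum(melting_temperature(p) for p in primers) / len(primers)


def design_inhibitor(
    consensus: ConsensusMotif | NucSequence | str,
    primers: list[Oligo],
    params: DesignParams = DesignParams(),
    microbial_refs: dict[str, str] | None = None,
) -> InhibitorDesign:
    """Design a 3'-C3-spacer blocking oligo from the reduced consensus.

    The candidate is a 5'-anchored prefix of the reduced consensus (which
    by construction starts immediately downstream of the primer-like
    region).  With ``explicit_length`` set, that prefix is taken verbatim;
    otherwise the shortest length in ``length_range`` whose Tm falls
    within ``tm_window`` of the mean primer Tm is chosen.  The design is
    accepted iff it satisfies the Tm window, forms no hairpin, and has no
    priming-competent site on ``microbial_refs``.
    """
    if isinstance(consensus, ConsensusMotif):
        source = consensus.iupac_reduced
        if source is None:
            raise ValueError("consensus motif has no reduced IUPAC string; "
                             "run call_iupac_consensus first")
    else:
        source = NucSequence(consensus)
    lo, hi = params.length_range
    needed = params.explicit_length if params.explicit_length is not None else lo
    if len(source) < needed:
        raise ValueError(
            f"reduced consensus (length {len(source)}) is shorter than the "
            f"required design length {needed}"
        )
    target_tm = _mean_primer_tm(primers)

    if params.explicit_length is not None:
        length = params.explicit_length
        seq = NucSequence(str(source)[:length])
        tm = melting_temperature(seq)
    else:
        chosen: tuple[int, NucSequence, float] | None = None
        best: tuple[float, int, NucSequence, float] | None = None
        for length in range(lo, min(hi, len(source)) + 1):
            cand = NucSequence(str(source)[:length])
            cand_tm = melting_temperature(cand)
            dev = abs(cand_tm - target_tm)
            if best is None or dev < best[0]:
                best = (dev, length, cand, cand_tm)
            if dev <= params.tm_window:
                chosen = (length, cand, cand_tm)
                break
        if chosen is None:
            assert best is not None
            raise ValueError(
                f"no prefix length in {params.length_range} meets the Tm "
                f"window of ±{params.tm_window} °C around {target_tm:.1f} °C; "
                f"closest candidate is the {best[1]}-mer {best[2]} with "
                f"ΔTm {best[3] - target_tm:+.1f} °C"
            )
        length, seq, tm = chosen

    oligo = Oligo(
        name=f"inhibitor-{length}mer",
        seq=seq,
        role=OligoRole.inhibitor,
        three_prime_mod=ThreePrimeMod.C3_spacer,
    )
    hairpin = hairpin_scan(oligo)
    cross: tuple = ()
    if microbial_refs:
        cross = tuple(
            screen_cross_reactivity(
                oligo, microbial_refs,
                max_mismatch=params.max_mismatch, anchor_len=params.anchor_len,
            )
        )
    delta = tm - target_tm
    accepted = (
        abs(delta) <= params.tm_window
        and not hairpin.has_hairpin
        and len(cross) == 0
    )
    return InhibitorDesign(
        oligo=oligo,
        tm=tm,
        delta_tm=delta,
        hairpin=hairpin,
        cross_hits=cross,
        accepted=accepted,
        primer_tm_mean=target_tm,
        tm_window=params.tm_window,
    )


def screen_cross_reactivity(
    oligo: Oligo,
    references: dict[str, str],
    max_mismatch: int = 3,
    anchor_len: int = 5,
) -> list[tuple[str, int, int]]:
    """Find every site where the oligo could anneal primer-like on a
    reference set (anchor-perfect 3' end, <= ``max_mismatch`` elsewhere,
    both strands).  An empty list means the oligo is specific.

    Returns (reference id, 1-based position, n_mismatches) tuples.
    """
    if not references or any(len(str(s)) == 0 for s in references.values()):
        raise ValueError("reference set must be non-empty sequences")
    params = ScanParams(anchor_len=anchor_len, max_mismatches=max_mismatch)
    sites = scan_priming_sites(references, oligo, params)
    return [(s.chrom, s.pos_1based, s.n_mismatches) for s in sites]
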