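"""Synthetic study system with known ground truth.

Everything the pipeline consumes can be generated here: a host genome
carrying planted mis-priming loci (primer-like landings with perfect 3'
ends flanking the 5'/3' consensus motifs in convergent orientation), a
mock 16S community with Dirichlet abundances, low-copy kitome
contaminant templates, and PCR-simulated amplicon reads.

The PCR model is deterministic exponential amplification followed by
multinomial sampling: template *t* with initial copies ``T_t`` and
per-cycle efficiency

    e_t = e0 * rho**m_t * (1 - inhibitor_binding * I_t)

(``m_t`` = planted non-anchor primer mismatches, ``I_t`` = 1 if the
blocking oligo anchor-matches immediately downstream of the template's
forward landing) reaches final weight ``W_t = T_t * (1 + e_t)**cycles``;
reads are drawn multinomially from ``W / sum(W)`` and substitution errors
applied per base.  Host mis-priming sites carry mismatches (small ``e``),
16S templates amplify at full efficiency, so host DNA only wins through
sheer template excess — the host-dominated biopsy regime.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .community_bias import FeatureTable
from .inhibitor import screen_cross_reactivity
from .mispriming import ScanParams, scan_priming_sites
from .primers import (
    FIVE_PRIME_CONSENSUS_REDUCED,
    INHIBITOR_24MER,
    PRIMER_341F,
    PRIMER_805R,
    THREE_PRIME_MOTIFS,
)
from .seqcore import (
    IUPAC_SETS,
    NucSequence,
    Oligo,
    expand_degenerate,
    reverse_complement,
)

__all__ = [
    "PlantedLocus",
    "PlantedLocusTruth",
    "SimConfig",
    "SimulatedSample",
    "make_host_genome",
    "make_16s_community",
    "simulate_pcr_reads",
    "simulate_offtarget_reads",
    "make_feature_tables",
    "expected_fractions",
]

_BASES = "ACGT"
_DEFAULT_SCAN = ScanParams()


@dataclass(frozen=True)
class PlantedLocus:
    """Specification of one off-target locus to plant.

    Forward-strand layout (5'->3'):
    [341F-like landing][5' motif][spacer][revcomp 3' motif][revcomp 805R-like landing]

    Mismatch offsets are 3'-relative distances (vs the respective primer)
    and must stay outside the scanner's default 3' anchor so the planted
    site is recoverable.  ``product_len`` fixes the spacer length.
    """

    chrom: str
    fwd_mismatch_offsets: tuple[int, ...] = (7, 12)
    rev_mismatch_offsets: tuple[int, ...] = (6, 11)
    five_prime_motif: NucSequence = FIVE_PRIME_CONSENSUS_REDUCED
    three_prime_motif: NucSequence = THREE_PRIME_MOTIFS["chr5"]
    product_len: int = 248

    @property
    def spacer_len(self) -> int:
        inner = (
            len(PRIMER_341F.seq)
            + len(self.five_prime_motif)
            + len(self.three_prime_motif)
            + len(PRIMER_805R.seq)
        )
        return self.product_len - inner

    def __post_init__(self) -> None:
        if self.spacer_len < 0:
            raise ValueError("product_len too short for the motif layout")
        anchor = _DEFAULT_SCAN.anchor_len
        if any(o < anchor for o in self.fwd_mismatch_offsets + self.rev_mismatch_offsets):
            raise ValueError(
                f"planted mismatch offsets must be >= the scanner anchor ({anchor})"
            )


def _default_loci() -> tuple[PlantedLocus, ...]:
    return tuple(
        PlantedLocus(chrom=f"chr{tag}", three_prime_motif=motif)
        for tag, motif in (("5", THREE_PRIME_MOTIFS["chr5"]),
                           ("11", THREE_PRIME_MOTIFS["chr11"]),
                           ("17", THREE_PRIME_MOTIFS["chr17"])))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic system.

    Copy numbers describe the host-dominated biopsy regime: ~1e8 host
    genome equivalents per locus against ~1e3 microbial 16S templates,
    which together with the mismatch-penalized host efficiency puts the
    default off-target read fraction in the tens of percent.  ``cycles``
    is 25 (standard library prep); 35 models the contaminant-enhancing
    second-round design.
    """

    seed: int = 0
    n_chrom: int = 3
    chrom_len: int = 50_000
    loci: tuple[PlantedLocus, ...] = field(default_factory=_default_loci)
    n_taxa: int = 20
    dirichlet_alpha: float = 1.0
    n_kitome: int = 3
    host_template_copies: float = 1e8
    microbial_template_copies: float = 1e3
    kitome_template_copies: float = 5.0
    cycles: int = 25
    base_efficiency: float = 0.95
    mismatch_penalty: float = 0.6
    inhibitor_binding: float = 0.0
    error_rate: float = 0.005
    depth: int = 50_000
    insert_len: int = 427

    def __post_init__(self) -> None:
        for name in ("base_efficiency", "mismatch_penalty", "inhibitor_binding",
                     "error_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.cycles < 1 or self.depth < 1:
            raise ValueError("cycles and depth must be >= 1")


@dataclass(frozen=True)
class PlantedLocusTruth:
    """Realized coordinates and sequences of one planted locus."""

    spec: PlantedLocus
    chrom: str
    product_start: int  # 0-based
    product_end: int
    fwd_start: int
    rev_start: int
    fwd_mismatch_offsets: tuple[int, ...]
    rev_mismatch_offsets: tuple[int, ...]
    five_prime_concrete: NucSequence
    amplicon_seq: NucSequence

    @property
    def product_len(self) -> int:
        return self.product_end - self.product_start


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(_BASES))[rng.integers(0, 4, size=n)])


def _concretize_cycle(seq: str, index: int) -> str:
    """Resolve degenerate positions deterministically, cycling through the
    sorted base set by locus index (keeps e.g. an S column balanced across
    the planted locus variants)."""
    out = []
    for c in seq:
        bases = sorted(IUPAC_SETS[c])
        out.append(bases[index % len(bases)] if len(bases) > 1 else c)
    return "".join(out)


def _mutate_landing(concrete: str, primer: Oligo, offsets_3p: tuple[int, ...],
                    rng: np.random.Generator) -> str:
    """Substitute bases at the given 3'-relative offsets so they no longer
    match the primer's IUPAC code at that position."""
    s = list(concrete)
    L = len(s)
    for off in offsets_3p:
        idx = L - 1 - off
        allowed = [b for b in _BASES if b not in IUPAC_SETS[primer.seq[idx]]]
        if not allowed:
            raise ValueError(
                f"cannot plant a mismatch at 3'-offset {off} of {primer.name}: "
                f"the primer base there is {primer.seq[idx]!r} (matches any base)"
            )
        s[idx] = allowed[int(rng.integers(0, len(allowed)))]
    return "".join(s)


def _locus_cassette(spec: PlantedLocus, index: int,
                    rng: np.random.Generator) -> tuple[str, NucSequence]:
    fwd_exp = _concretize_cycle(str(PRIMER_341F.seq), index)
    fwd_landing = _mutate_landing(fwd_exp, PRIMER_341F, spec.fwd_mismatch_offsets, rng)
    five = _concretize_cycle(str(spec.five_prime_motif), index)
    spacer = _random_seq(rng, spec.spacer_len)
    three_rc = str(reverse_complement(spec.three_prime_motif))
    rev_exp = _concretize_cycle(str(PRIMER_805R.seq), index)
    rev_landing = _mutate_landing(rev_exp, PRIMER_805R, spec.rev_mismatch_offsets, rng)
    cassette = fwd_landing + five + spacer + three_rc + str(reverse_complement(rev_landing))
    assert len(cassette) == spec.product_len
    return cassette, NucSequence(five)


def make_host_genome(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], list[PlantedLocusTruth]]:
    """Generate a host genome with planted mis-priming loci and its truth.

    Backgrounds are uniform-random and screened at generation time: a
    chromosome is regenerated (up to 100 attempts) until the only primer
    sites the scanner finds at default parameters are the planted ones.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    by_chrom: dict[str, list[tuple[int, PlantedLocus]]] = {}
    for i, spec in enumerate(config.loci):
        by_chrom.setdefault(spec.chrom, []).append((i, spec))
    chrom_names = sorted(set(by_chrom) | {f"chr{i + 1}" for i in
                                          range(config.n_chrom - len(by_chrom))})
    genome: dict[str, str] = {}
    truths: list[PlantedLocusTruth] = []
    for chrom in chrom_names:
        planted = by_chrom.get(chrom, [])
        total_cassette = sum(s.product_len for _, s in planted)
        if total_cassette > config.chrom_len:
            raise ValueError(f"loci do not fit on {chrom} ({config.chrom_len} bp)")
        for attempt in range(100):
            seq, chrom_truths = _build_chromosome(chrom, planted, config, rng)
            if _is_clean(chrom, seq, chrom_truths):
                genome[chrom] = seq
                truths.extend(chrom_truths)
                break
        else:
            raise RuntimeError(
                f"could not generate a clean background for {chrom} in 100 attempts"
            )
    truths.sort(key=lambda t: (t.chrom, t.product_start))
    return genome, truths


def _build_chromosome(chrom, planted, config, rng):
    n_loci = len(planted)
    free = config.chrom_len - sum(s.product_len for _, s in planted)
    # evenly spaced plantings with jitter
    cuts = np.sort(rng.integers(0, free + 1, size=n_loci)) if n_loci else []
    seq_parts: list[str] = []
    truths: list[PlantedLocusTruth] = []
    prev_cut = 0
    pos = 0
    for (idx, spec), cut in zip(planted, cuts):
        bg = _random_seq(rng, int(cut) - prev_cut)
        seq_parts.append(bg)
        pos += len(bg)
        cassette, five = _locus_cassette(spec, idx, rng)
        truths.append(
            PlantedLocusTruth(
                spec=spec,
                chrom=chrom,
                product_start=pos,
                product_end=pos + spec.product_len,
                fwd_start=pos,
                rev_start=pos + spec.product_len - len(PRIMER_805R.seq),
                fwd_mismatch_offsets=tuple(sorted(spec.fwd_mismatch_offsets)),
                rev_mismatch_offsets=tuple(sorted(spec.rev_mismatch_offsets)),
                five_prime_concrete=five,
                amplicon_seq=NucSequence(cassette),
            )
        )
        seq_parts.append(cassette)
        pos += spec.product_len
        prev_cut = int(cut)
    seq_parts.append(_random_seq(rng, free - prev_cut))
    return "".join(seq_parts), truths


def _is_clean(chrom: str, seq: str, truths: list[PlantedLocusTruth]) -> bool:
    """True iff default-parameter scans find exactly the planted sites."""
    expected = set()
    for t in truths:
        expected.add(("341F", t.fwd_start, "+"))
        expected.add(("805R", t.rev_start, "-"))
    found = set()
    for primer in (PRIMER_341F, PRIMER_805R):
        for s in scan_priming_sites({chrom: seq}, primer, _DEFAULT_SCAN):
            found.add((s.primer_name, s.start, s.strand))
    return found == expected


def make_16s_community(
    config: SimConfig,
    rng: np.random.Generator | None = None,
    n_templates: int | None = None,
    prefix: str = "taxon",
) -> tuple[dict[str, str], np.ndarray]:
    """Mock 16S templates with Dirichlet abundances.

    Each template is a concrete 341F expansion + random insert +
    reverse-complemented 805R expansion (V3-V4-like product).  Inserts
    are screened at generation time so no template contains the 5'
    off-target consensus or a priming-competent site for the blocking
    oligo.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_taxa if n_templates is None else n_templates
    if n < 1:
        raise ValueError("need at least one taxon")
    templates: dict[str, str] = {}
    fwd_expansions = expand_degenerate(PRIMER_341F.seq)
    rev_expansions = expand_degenerate(PRIMER_805R.seq)
    for i in range(n):
        fwd = fwd_expansions[int(rng.integers(0, len(fwd_expansions)))]
        rev = rev_expansions[int(rng.integers(0, len(rev_expansions)))]
        for _ in range(100):
            insert = _random_seq(rng, config.insert_len)
            tpl = str(fwd) + insert + str(reverse_complement(rev))
            if _template_is_clean(tpl):
                break
        else:
            raise RuntimeError("could not generate a clean 16S template")
        templates[f"{prefix}_{i + 1:03d}"] = tpl
    abund = rng.dirichlet(np.full(n, config.dirichlet_alpha))
    return templates, abund


def _template_is_clean(tpl: str) -> bool:
    from .consensus import locate_motif

    if locate_motif(FIVE_PRIME_CONSENSUS_REDUCED, {"t": tpl}, max_mismatch=2):
        return False
    return not screen_cross_reactivity(INHIBITOR_24MER, {"t": tpl})


@dataclass
class SimulatedSample:
    """Reads plus per-template and per-read truth for one PCR + run."""

    reads: list[tuple[str, str, str]]  # (read id, sequence, quality)
    read_sources: list[str]  # template id per read
    template_truth: pd.DataFrame  # per-template copies, efficiency, weight, fraction

    @property
    def offtarget_fraction(self) -> float:
        n = sum(src.startswith("host_") for src in self.read_sources)
        return n / len(self.read_sources) if self.read_sources else 0.0


def _inhibitor_blocks(template: str, inhibitor: Oligo = INHIBITOR_24MER) -> bool:
    """True iff the blocking oligo anchor-matches immediately downstream
    of the template's forward-primer landing (template position 1-based
    len(341F)+1, plus strand)."""
    hits = screen_cross_reactivity(inhibitor, {"t": template})
    target_pos = len(PRIMER_341F.seq) + 1
    return any(pos == target_pos for _rid, pos, _mm in hits)


def expected_fractions(
    templates: dict[str, str],
    copies: dict[str, float],
    mismatches: dict[str, int],
    config: SimConfig,
) -> pd.DataFrame:
    """Closed-form per-template read fractions W_t / sum(W).

    Columns: copies, n_mismatches, inhibited, efficiency, weight, fraction.
    """
    rows = []
    for tid, tpl in templates.items():
        m = mismatches.get(tid, 0)
        inhibited = config.inhibitor_binding > 0 and _inhibitor_blocks(tpl)
        eff = (config.base_efficiency * config.mismatch_penalty ** m
               * (1 - (config.inhibitor_binding if inhibited else 0.0)))
        w = copies[tid] * (1 + eff) ** config.cycles
        rows.append({"template_id": tid, "copies": copies[tid], "n_mismatches": m,
                     "inhibited": inhibited, "efficiency": eff, "weight": w})
    df = pd.DataFrame(rows).set_index("template_id")
    total = df["weight"].sum()
    if total <= 0:
        raise ValueError("all template weights are zero")
    df["fraction"] = df["weight"] / total
    return df


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hit:
        choices = [b for b in b"ACGT" if b != arr[i]]
        arr[i] = choices[int(rng.integers(0, 3))]
    return arr.tobytes().decode("ascii")


def simulate_pcr_reads(
    host_truth: list[PlantedLocusTruth],
    community: dict[str, str],
    abundances: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    kitome: dict[str, str] | None = None,
    kitome_abund: np.ndarray | None = None,
    host_copy_factor: float = 1.0,
) -> SimulatedSample:
    """Draw one sample's reads from the closed-form template weights.

    Quality strings are constant Phred 35.  ``host_copy_factor`` scales
    the host template copy number, modeling between-sample variability in
    host DNA load.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    templates: dict[str, str] = {}
    copies: dict[str, float] = {}
    mism: dict[str, int] = {}
    for i, t in enumerate(host_truth):
        tid = f"host_{t.chrom}_{t.product_start}"
        templates[tid] = str(t.amplicon_seq)
        copies[tid] = config.host_template_copies * host_copy_factor
        mism[tid] = len(t.fwd_mismatch_offsets) + len(t.rev_mismatch_offsets)
    for (tid, tpl), a in zip(community.items(), abundances):
        templates[tid] = tpl
        copies[tid] = config.microbial_template_copies * float(a)
        mism[tid] = 0
    if kitome:
        ka = (kitome_abund if kitome_abund is not None
              else np.full(len(kitome), 1.0 / len(kitome)))
        for (tid, tpl), a in zip(kitome.items(), ka):
            templates[tid] = tpl
            copies[tid] = config.kitome_template_copies * float(a)
            mism[tid] = 0

    truth = expected_fractions(templates, copies, mism, config)
    ids = list(truth.index)
    n_per = rng.multinomial(config.depth, truth["fraction"].to_numpy())
    reads: list[tuple[str, str, str]] = []
    sources: list[str] = []
    r = 0
    for tid, k in zip(ids, n_per):
        tpl = templates[tid]
        for _ in range(int(k)):
            seq = _apply_errors(tpl, config.error_rate, rng)
            reads.append((f"read_{r:06d}", seq, "D" * len(seq)))
            sources.append(tid)
            r += 1
    return SimulatedSample(reads=reads, read_sources=sources, template_truth=truth)


def simulate_offtarget_reads(
    n_reads: int = 120,
    error_rate: float = 0.01,
    seed: int = 0,
    motif: NucSequence = FIVE_PRIME_CONSENSUS_REDUCED,
    read_len: int = 60,
) -> list[NucSequence]:
    """Primer-trimmed off-target read 5' ends from the three locus variants.

    Reads are assigned round-robin to three locus variants whose motif
    degeneracies are resolved cyclically (so an S column is drawn C/G in
    balanced proportion), followed by random downstream sequence, with
    substitution noise applied per base.
    """
    rng = np.random.default_rng(seed)
    variants = [_concretize_cycle(str(motif), i) for i in range(3)]
    tails = [_random_seq(rng, max(0, read_len - len(motif))) for _ in range(3)]
    out: list[NucSequence] = []
    for i in range(n_reads):
        v = i % 3
        seq = _apply_errors(variants[v] + tails[v], error_rate, rng)
        out.append(NucSequence(seq))
    return out


def make_feature_tables(
    samples: dict[str, SimulatedSample],
    templates: dict[str, str],
    taxonomy_phyla: tuple[str, ...] = ("Bacillota", "Bacteroidota", "Pseudomonadota"),
) -> tuple[FeatureTable, set[str]]:
    """Build the ASV-style feature table from simulated samples.

    Features are the error-free template sequences (what denoising would
    recover); counts come from the per-read truth labels.  Returns the
    table (with taxonomy for microbial and kitome features) and the set
    of host feature ids.
    """
    template_ids = list(templates)
    counts = pd.DataFrame(0, index=template_ids, columns=list(samples), dtype=int)
    for sid, sample in samples.items():
        vc = pd.Series(sample.read_sources).value_counts()
        counts.loc[vc.index, sid] = vc.values
    host_ids = {t for t in template_ids if t.startswith("host_")}
    tax_rows = {}
    for i, tid in enumerate(template_ids):
        if tid in host_ids:
            continue
        genus = f"Kitome_{tid.split('_')[-1]}" if tid.startswith("kit") else f"Genus_{tid.split('_')[-1]}"
        tax_rows[tid] = {
            "phylum": taxonomy_phyla[i % len(taxonomy_phyla)],
            "genus": genus,
            "organelle": False,
        }
    taxonomy = pd.DataFrame.from_dict(tax_rows, orient="index")
    return FeatureTable(counts=counts, taxonomy=taxonomy), host_ids
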