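"""Partition amplicon features into host off-targets vs microbial reads.

ASVs (amplicon sequence variants) are aligned against the host reference;
a feature whose best hit clears the identity and coverage thresholds is
labeled a host off-target, everything else is treated as putative
microbial sequence.  Off-targets are then tallied per chromosome
(read-weighted) and their 5' mapping positions clustered into recurrent
loci.

Alignment comes either from the built-in k-mer-seeded ungapped aligner
(adequate at desk scale) or from an external aligner's SAM file.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass

import pandas as pd
import pysam

from .seqcore import NucSequence, reverse_complement

__all__ = [
    "AlignmentHit",
    "ClassifiedFeature",
    "PositionCluster",
    "align_feature",
    "classify_features",
    "ingest_sam",
    "cluster_positions",
    "chromosome_report",
]

logger = logging.getLogger(__name__)

DEFAULT_IDENTITY_MIN = 0.95
DEFAULT_COVERAGE_MIN = 0.90
DEFAULT_SEED_LEN = 16


@dataclass(frozen=True)
class AlignmentHit:
    """Best ungapped placement of a query on the host reference."""

    query_id: str
    chrom: str
    start: int  # 0-based leftmost
    strand: str
    aligned_len: int
    identity: float
    coverage: float

    @property
    def end(self) -> int:
        return self.start + self.aligned_len

    @property
    def five_prime_pos(self) -> int:
        """1-based genomic coordinate of the query's biological 5' end
        (leftmost base on '+', rightmost on '-')."""
        return self.start + 1 if self.strand == "+" else self.end


@dataclass(frozen=True)
class ClassifiedFeature:
    feature_id: str
    label: str  # "host_offtarget" | "non_host"
    best_hit: AlignmentHit | None
    read_weight: float


@dataclass(frozen=True)
class PositionCluster:
    """A recurrent 5'-mapping locus of host off-targets."""

    chrom: str
    strand: str
    mode_start: int  # 1-based, most read-weighted 5' coordinate
    total_reads: float
    n_features: int
    member_positions: tuple[int, ...]


def _build_index(host_ref: dict[str, str], k: int) -> dict[str, list[tuple[str, int]]]:
    index: dict[str, list[tuple[str, int]]] = defaultdict(list)
    for chrom in sorted(host_ref):
        seq = str(host_ref[chrom]).upper()
        for i in range(len(seq) - k + 1):
            kmer = seq[i: i + k]
            if "N" not in kmer:
                index[kmer].append((chrom, i))
    return index


def align_feature(
    seq: NucSequence | str,
    host_ref: dict[str, str],
    seed_len: int = DEFAULT_SEED_LEN,
    max_mismatch_rate: float = 0.25,
    _index: dict | None = None,
) -> AlignmentHit | None:
    """k-mer-seeded ungapped alignment of one query against the reference.

    Every exact ``seed_len``-mer shared between query (either strand) and
    reference anchors a candidate ungapped placement, which is scored over
    the overlap of query and chromosome.  The best hit by (identity,
    aligned_len) is returned, ties broken by (chrom, start, '+' first);
    ``None`` when no seed matches or the best candidate exceeds
    ``max_mismatch_rate``.
    """
    q = str(seq).upper()
    if len(q) < seed_len:
        raise ValueError(
            f"query of length {len(q)} is shorter than the seed length {seed_len}"
        )
    index = _index if _index is not None else _build_index(host_ref, seed_len)
    qlen = len(q)
    scored: list[tuple[tuple, AlignmentHit]] = []
    for strand in ("+", "-"):
        qs = q if strand == "+" else str(reverse_complement(q))
        candidates: set[tuple[str, int]] = set()
        for off in range(qlen - seed_len + 1):
            for chrom, pos in index.get(qs[off: off + seed_len], ()):
                candidates.add((chrom, pos - off))
        for chrom, start in candidates:
            ref = str(host_ref[chrom]).upper()
            lo = max(start, 0)
            hi = min(start + qlen, len(ref))
            if hi <= lo:
                continue
            qseg = qs[lo - start: hi - start]
            rseg = ref[lo:hi]
            matches = sum(a == b for a, b in zip(qseg, rseg))
            aligned = hi - lo
            identity = matches / aligned
            if 1 - identity > max_mismatch_rate:
                continue
            hit = AlignmentHit(
                query_id="", chrom=chrom, start=lo, strand=strand,
                aligned_len=aligned, identity=identity, coverage=aligned / qlen,
            )
            # best by (identity, aligned_len); ties by chrom, start, '+' first
            scored.append(((-identity, -aligned, chrom, lo, strand != "+"), hit))
    if not scored:
        return None
    return min(scored, key=lambda t: t[0])[1]


def classify_features(
    features: dict[str, str],
    table: pd.DataFrame,
    host_ref: dict[str, str],
    identity_min: float = DEFAULT_IDENTITY_MIN,
    coverage_min: float = DEFAULT_COVERAGE_MIN,
    seed_len: int = DEFAULT_SEED_LEN,
) -> list[ClassifiedFeature]:
    """Label every tabulated feature as host off-target or non-host.

    ``features`` maps feature id -> sequence; ``table`` is the feature x
    sample count table.  A feature is a host off-target iff its best hit
    reaches ``identity_min`` identity over ``coverage_min`` of the query.
    """
    missing = [fid for fid in table.index if fid not in features]
    if missing:
        raise ValueError(f"features without sequences: {missing[:5]}")
    index = _build_index(host_ref, seed_len)
    out: list[ClassifiedFeature] = []
    for fid in table.index:
        hit = align_feature(features[fid], host_ref, seed_len=seed_len, _index=index)
        weight = float(table.loc[fid].sum())
        if hit is not None and hit.identity >= identity_min and hit.coverage >= coverage_min:
            hit = AlignmentHit(
                query_id=fid, chrom=hit.chrom, start=hit.start, strand=hit.strand,
                aligned_len=hit.aligned_len, identity=hit.identity, coverage=hit.coverage,
            )
            out.append(ClassifiedFeature(fid, "host_offtarget", hit, weight))
        else:
            out.append(ClassifiedFeature(fid, "non_host", None, weight))
    return out


def ingest_sam(path: str, table: pd.DataFrame) -> list[ClassifiedFeature]:
    """Build the host/non-host partition from an external aligner's SAM.

    Mapped primary records become host off-targets (chrom=RNAME, 0-based
    start=POS-1, strand from FLAG 0x10); unmapped records become non-host.
    Secondary (0x100) and supplementary (0x800) records are ignored.
    Records whose QNAME is absent from the table are skipped with a
    warning.
    """
    n_header = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("@"):
                n_header += 1
            else:
                break
    out: list[ClassifiedFeature] = []
    seen: set[str] = set()
    skipped = 0
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        for i, rec in enumerate(sam):
            try:
                if rec.is_secondary or rec.is_supplementary:
                    continue
                qname = rec.query_name
                if qname not in table.index:
                    logger.warning("SAM record %r not in feature table; skipped", qname)
                    skipped += 1
                    continue
                if qname in seen:
                    continue
                seen.add(qname)
                weight = float(table.loc[qname].sum())
                if rec.is_unmapped:
                    out.append(ClassifiedFeature(qname, "non_host", None, weight))
                    continue
                qlen = rec.query_length or (rec.infer_query_length() or 0)
                aligned = rec.query_alignment_length or qlen
                hit = AlignmentHit(
                    query_id=qname,
                    chrom=rec.reference_name,
                    start=rec.reference_start,
                    strand="-" if rec.is_reverse else "+",
                    aligned_len=rec.reference_length or aligned,
                    identity=1.0,
                    coverage=(aligned / qlen) if qlen else 1.0,
                )
                out.append(ClassifiedFeature(qname, "host_offtarget", hit, weight))
            except (ValueError, KeyError) as exc:  # malformed record
                raise ValueError(
                    f"malformed SAM record near line {n_header + i + 1} "
                    f"of {path}: {exc}"
                ) from exc
    # features never mentioned in the SAM default to non-host
    for fid in table.index:
        if fid not in seen:
            out.append(ClassifiedFeature(fid, "non_host", None, float(table.loc[fid].sum())))
    order = {fid: i for i, fid in enumerate(table.index)}
    out.sort(key=lambda f: order[f.feature_id])
    if skipped:
        logger.warning("%d SAM records skipped (unknown feature ids)", skipped)
    return out


def cluster_positions(
    classified: list[ClassifiedFeature], tolerance: int = 5
) -> list[PositionCluster]:
    """Single-linkage clustering of off-target 5' positions per
    (chrom, strand), gap <= ``tolerance``; clusters ranked by total read
    weight descending."""
    by_locus: dict[tuple[str, str], list[tuple[int, float]]] = defaultdict(list)
    for f in classified:
        if f.label != "host_offtarget" or f.best_hit is None:
            continue
        h = f.best_hit
        by_locus[(h.chrom, h.strand)].append((h.five_prime_pos, f.read_weight))
    clusters: list[PositionCluster] = []
    for (chrom, strand), members in by_locus.items():
        members.sort()
        group: list[tuple[int, float]] = []
        for pos, w in members:
            if group and pos - group[-1][0] > tolerance:
                clusters.append(_finish_cluster(chrom, strand, group))
                group = []
            group.append((pos, w))
        if group:
            clusters.append(_finish_cluster(chrom, strand, group))
    clusters.sort(key=lambda c: (-c.total_reads, c.chrom, c.mode_start))
    return clusters


def _finish_cluster(chrom: str, strand: str, group: list[tuple[int, float]]) -> PositionCluster:
    weights: dict[int, float] = defaultdict(float)
    for pos, w in group:
        weights[pos] += w
    mode = max(weights, key=lambda p: (weights[p], -p))
    return PositionCluster(
        chrom=chrom,
        strand=strand,
        mode_start=mode,
        total_reads=sum(w for _, w in group),
        n_features=len(group),
        member_positions=tuple(p for p, _ in group),
    )


def chromosome_report(classified: list[ClassifiedFeature]) -> pd.DataFrame:
    """Read-weighted off-target counts per chromosome (descending)."""
    counts: dict[str, float] = defaultdict(float)
    for f in classified:
        if f.label == "host_offtarget" and f.best_hit is not None:
            counts[f.best_hit.chrom] += f.read_weight
    df = pd.DataFrame(
        {"chrom": list(counts), "offtarget_reads": list(counts.values())}
    )
    if not df.empty:
        df = df.sort_values("offtarget_reads", ascending=False, ignore_index=True)
    return df
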