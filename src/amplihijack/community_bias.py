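"""Community-analysis bias introduced by retaining host off-targets.

Host off-target reads inflate per-sample denominators, depress every
microbial relative abundance, burn sequencing depth (pushing samples
below rarefaction saturation), and perturb ordination.  This module
quantifies each effect on a feature x sample count table:

* genus-level abundance/prevalence filtering with an audit log;
* with/without-off-target relative-abundance comparison;
* analytic (expected-value) rarefaction with a saturation rule
  (final slope below a genera-per-read threshold);
* PCoA on Hellinger distances (Euclidean distance on square-root
  transformed relative abundances).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.special import gammaln
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa

__all__ = [
    "FeatureTable",
    "FilterParams",
    "FilterResult",
    "RarefactionResult",
    "OrdinationResult",
    "filter_features",
    "compare_with_without",
    "relative_abundance",
    "rarefaction_curve",
    "hellinger_pcoa",
    "hellinger_distances",
    "mean_distance_to_centroid",
]

logger = logging.getLogger(__name__)

HOST_TAXON = "host_offtarget"
_UNASSIGNED = "Unassigned"


@dataclass
class FeatureTable:
    """Feature x sample integer counts with optional taxonomy.

    ``taxonomy`` (indexed by feature id) may carry columns ``phylum``,
    ``genus`` and a boolean ``organelle`` flag; it needs to cover only a
    subset of the features.  Features without a genus label aggregate
    into their own singleton groups.
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates or c.columns.has_duplicates:
            raise ValueError("feature and sample ids must be unique")
        if (c.values < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def genus_of(self, feature_id: str) -> str:
        if self.taxonomy is not None and feature_id in self.taxonomy.index:
            g = self.taxonomy.loc[feature_id].get("genus")
            if isinstance(g, str) and g:
                return g
        return f"feature:{feature_id}"

    def genus_table(self) -> pd.DataFrame:
        """Counts aggregated to genus level (samples as columns)."""
        genera = [self.genus_of(f) for f in self.counts.index]
        return self.counts.groupby(pd.Index(genera, name="genus")).sum()

    def subset(self, feature_ids: list[str]) -> "FeatureTable":
        tax = None
        if self.taxonomy is not None:
            tax = self.taxonomy.loc[self.taxonomy.index.intersection(feature_ids)]
        return FeatureTable(self.counts.loc[feature_ids].copy(), tax)

    def partition(self, host_ids: set[str]) -> tuple["FeatureTable", "FeatureTable"]:
        """(host subset, non-host subset); the two partitions are disjoint
        and jointly cover every feature."""
        host = [f for f in self.counts.index if f in host_ids]
        rest = [f for f in self.counts.index if f not in host_ids]
        return self.subset(host), self.subset(rest)


@dataclass(frozen=True)
class FilterParams:
    """Genus-level abundance/prevalence filter thresholds.

    A genus is kept iff its maximum per-sample relative abundance reaches
    ``max_abund_cutoff`` (default 0.01%) AND it occurs in at least
    ``prevalence_cutoff`` of the samples (default 1%).  Organelle
    (mitochondria/chloroplast) and phylum-unassigned features can be
    dropped first.
    """

    max_abund_cutoff: float = 1e-4
    prevalence_cutoff: float = 0.01
    drop_unassigned_phylum: bool = True
    drop_organelles: bool = True

    def __post_init__(self) -> None:
        for v in (self.max_abund_cutoff, self.prevalence_cutoff):
            if not (0 < v < 1):
                raise ValueError("cutoffs must lie in (0, 1)")


@dataclass
class FilterResult:
    table: FeatureTable
    log: pd.DataFrame  # columns: id, level, reason


@dataclass
class RarefactionResult:
    sample_id: str
    curve: list[tuple[int, float]]
    final_slope: float | None
    saturated: bool | None
    evaluable: bool = True


@dataclass
class OrdinationResult:
    """Hellinger-distance PCoA of a community table."""

    distance_matrix: pd.DataFrame
    coordinates: pd.DataFrame
    eigenvalues: np.ndarray  # descending, negatives included for audit
    proportion_explained: np.ndarray  # over positive eigenvalues only


def filter_features(table: FeatureTable, params: FilterParams = FilterParams()) -> FilterResult:
    """Apply the taxonomy and genus-level abundance/prevalence filters.

    Removals are recorded with their reason; the operation is idempotent
    because removing below-threshold genera can only raise the relative
    abundance of the genera that remain.
    """
    log_rows: list[dict] = []
    keep = list(table.counts.index)

    if (params.drop_unassigned_phylum or params.drop_organelles) and table.taxonomy is None:
        raise ValueError("taxonomy-based drops requested but no taxonomy present")

    if table.taxonomy is not None:
        tax = table.taxonomy
        kept2 = []
        for f in keep:
            if f in tax.index:
                row = tax.loc[f]
                if params.drop_organelles and bool(row.get("organelle", False)):
                    log_rows.append({"id": f, "level": "feature", "reason": "organelle"})
                    continue
                phylum = row.get("phylum")
                if params.drop_unassigned_phylum and (
                    not isinstance(phylum, str) or not phylum or phylum == _UNASSIGNED
                ):
                    log_rows.append({"id": f, "level": "feature", "reason": "unassigned_phylum"})
                    continue
            kept2.append(f)
        keep = kept2

    sub = table.subset(keep)
    genus = sub.genus_table()
    totals = sub.counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = genus.div(totals.replace(0, np.nan), axis=1)
    max_rel = rel.max(axis=1).fillna(0.0)
    prevalence = (genus > 0).mean(axis=1)

    drop_genera: set[str] = set()
    for g in genus.index:
        if max_rel[g] < params.max_abund_cutoff:
            log_rows.append({"id": g, "level": "genus", "reason": "max_abundance"})
            drop_genera.add(g)
        elif prevalence[g] < params.prevalence_cutoff:
            log_rows.append({"id": g, "level": "genus", "reason": "prevalence"})
            drop_genera.add(g)

    final = [f for f in keep if sub.genus_of(f) not in drop_genera]
    if not final:
        raise ValueError("no features survive filtering")
    log = pd.DataFrame(log_rows, columns=["id", "level", "reason"])
    return FilterResult(table=table.subset(final), log=log)


def relative_abundance(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-sample relative abundances; zero-total samples become NaN."""
    totals = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return counts.div(totals.replace(0, np.nan), axis=1)


def compare_with_without(table: FeatureTable, host_ids: set[str]) -> pd.DataFrame:
    """Mean genus relative abundance with vs without host off-targets.

    The two modes differ only in whether host features enter the
    per-sample denominators; host reads are pooled into a single
    ``host_offtarget`` pseudo-taxon row (zero in removed mode), so each
    mode's per-sample abundances sum to 1.  Removing host reads can only
    raise microbial abundances, so ``delta`` >= 0 for every microbial
    taxon present.
    """
    unknown = host_ids - set(table.feature_ids)
    if unknown:
        raise ValueError(f"host ids absent from table: {sorted(unknown)[:5]}")
    host_tab, microb_tab = table.partition(host_ids)
    if microb_tab.counts.empty or len(microb_tab.counts.index) == 0:
        raise ValueError("host_ids cover every feature; nothing microbial remains")

    genus_microb = microb_tab.genus_table()
    host_row = host_tab.counts.sum(axis=0).rename(HOST_TAXON)
    retained_counts = pd.concat([genus_microb, host_row.to_frame().T])
    removed_counts = genus_microb

    rel_ret = relative_abundance(retained_counts)
    rel_rem = relative_abundance(removed_counts).reindex(retained_counts.index, fill_value=0.0)
    rel_rem.loc[HOST_TAXON] = 0.0

    out = pd.DataFrame(
        {
            "mean_retained": rel_ret.mean(axis=1, skipna=True),
            "mean_removed": rel_rem.mean(axis=1, skipna=True),
        }
    )
    out["delta"] = out["mean_removed"] - out["mean_retained"]
    out.index.name = "taxon"
    return out.sort_values("mean_removed", ascending=False)


def _expected_richness(n_per_genus: np.ndarray, depth: int) -> float:
    """E[number of genera observed in a uniform subsample of ``depth``
    reads without replacement] — the hypergeometric rarefaction formula
    E[S(n)] = sum_g (1 - C(N-N_g, n) / C(N, n))."""
    N = int(n_per_genus.sum())
    if depth > N:
        raise ValueError("depth exceeds total reads")
    ln_cNn = gammaln(N + 1) - gammaln(depth + 1) - gammaln(N - depth + 1)
    rest = N - n_per_genus
    with np.errstate(invalid="ignore"):
        ln_c = gammaln(rest + 1) - gammaln(depth + 1) - gammaln(rest - depth + 1)
    p_absent = np.where(rest >= depth, np.exp(ln_c - ln_cNn), 0.0)
    return float(np.sum(1.0 - p_absent))


def rarefaction_curve(
    sample_counts: pd.Series | dict,
    step: int = 100,
    threshold: float = 1e-4,
    sample_id: str = "",
) -> RarefactionResult:
    """Analytic rarefaction curve and saturation call for one sample.

    Expected genus richness is evaluated at depths step, 2*step, ...,
    and at the full depth N.  The final slope is the richness gained per
    read over the last ``step`` reads; the sample is saturated when that
    slope falls below ``threshold`` genera/read.  Samples with fewer than
    2*step reads are reported as unevaluable rather than dropped.
    """
    s = pd.Series(sample_counts, dtype=float)
    s = s[s > 0]
    n = s.to_numpy()
    N = int(n.sum())
    if N < 2 * step:
        logger.warning("sample %r has %d reads (< 2*step); unevaluable", sample_id, N)
        return RarefactionResult(sample_id, [], None, None, evaluable=False)
    depths = list(range(step, N + 1, step))
    if depths[-1] != N:
        depths.append(N)
    curve = [(d, _expected_richness(n, d)) for d in depths]
    e_final = _expected_richness(n, N)
    e_prev = _expected_richness(n, N - step)
    final_slope = (e_final - e_prev) / step
    return RarefactionResult(
        sample_id=sample_id,
        curve=curve,
        final_slope=final_slope,
        saturated=bool(final_slope < threshold),
    )


def hellinger_distances(counts: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Hellinger distances between samples (columns).

    Euclidean distance on square-root transformed relative abundances;
    the maximum, sqrt(2), is attained by samples sharing no taxa.
    """
    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total reads: {list(zero.index)}")
    hel = np.sqrt((counts / totals).to_numpy().T)  # samples x taxa
    dm = squareform(pdist(hel, metric="euclidean"))
    return pd.DataFrame(dm, index=counts.columns, columns=counts.columns)


def hellinger_pcoa(table: FeatureTable | pd.DataFrame, k: int = 2) -> OrdinationResult:
    """PCoA (classical metric scaling) on genus-level Hellinger distances.

    Coordinates are returned for the top ``k`` positive-eigenvalue axes;
    proportion explained is relative to the sum of positive eigenvalues.
    Hellinger distances are Euclidean-embeddable, so materially negative
    eigenvalues indicate a degenerate input and trigger a warning.
    """
    counts = table.genus_table() if isinstance(table, FeatureTable) else table
    if counts.shape[1] < 2:
        raise ValueError("at least 2 samples are required")
    dm = hellinger_distances(counts)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # skbio warns about negative eigenvalues
        ord_res = _skbio_pcoa(DistanceMatrix(dm.to_numpy(), ids=list(dm.index)),
                              method="eigh")
    eig = np.asarray(ord_res.eigvals, dtype=float)  # already descending
    scale = np.abs(eig).max() if len(eig) else 1.0
    if scale > 0 and eig.min() < -1e-8 * scale:
        warnings.warn(
            "materially negative PCoA eigenvalues for a Hellinger distance "
            "matrix; check the input table", stacklevel=2,
        )
    pos = eig > 0
    n_axes = min(k, int(pos.sum()))
    coords = ord_res.samples.iloc[:, :n_axes].copy()
    coords.index = dm.index
    prop = eig[pos] / eig[pos].sum() if pos.any() else np.array([])
    return OrdinationResult(
        distance_matrix=dm,
        coordinates=coords,
        eigenvalues=eig,
        proportion_explained=prop,
    )


def mean_distance_to_centroid(dm: pd.DataFrame) -> float:
    """Sample dispersion: mean distance to the group centroid, computed
    from the distance matrix via the Euclidean identity
    mean_i d(i, c)^2-free form (Gower): sum d^2 / (2 n^2) gives the mean
    squared distance to the centroid; we report its square root."""
    d2 = dm.to_numpy() ** 2
    n = d2.shape[0]
    msq = d2.sum() / (2 * n * n)
    return float(np.sqrt(msq))
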