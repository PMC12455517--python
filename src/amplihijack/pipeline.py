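"""End-to-end pipeline: scan -> predict -> classify -> cluster ->
consensus -> inhibitor design -> bias assessment.

``run_pipeline`` drives the stages over either a synthetic study system
(generated on the fly with known truth) or user-supplied inputs (genome
FASTA, ASV FASTA + count table, optional taxonomy and SAM), writing every
stage output plus a run manifest that records the seed, the effective
parameters and per-stage record counts — enough to reproduce the run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .community_bias import (
    FeatureTable,
    FilterParams,
    compare_with_without,
    filter_features,
    hellinger_pcoa,
    rarefaction_curve,
)
from .consensus import anchor_align, build_pfm, call_iupac_consensus
from .inhibitor import DesignParams, design_inhibitor
from .io import (
    amplicons_to_frame,
    read_fasta,
    read_feature_table,
    read_taxonomy,
    sites_to_frame,
    write_fasta,
    write_feature_table,
    write_fastq,
    write_sites_bed,
)
from .mispriming import ScanParams, predict_amplicons, scan_priming_sites
from .offtarget_classify import (
    chromosome_report,
    classify_features,
    cluster_positions,
    ingest_sam,
)
from .primers import PRIMER_341F, PRIMER_805R
from .seqcore import NucSequence, Oligo, OligoRole
from .synthetic_data import (
    SimConfig,
    make_16s_community,
    make_feature_tables,
    make_host_genome,
    simulate_pcr_reads,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


def _plain(obj):
    """Recursively reduce dataclass-derived structures to YAML-safe types."""
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, bool) or obj is None:
        return obj
    if isinstance(obj, (int, float)):
        return obj if type(obj) in (int, float) else float(obj)
    if isinstance(obj, str):
        return str(obj)
    return str(obj)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Effective configuration of a pipeline run.

    In synthetic mode (``simulate=True``) the inputs are generated from
    ``sim``; otherwise ``genome_path`` and ``features_path``/``table_path``
    must point at existing files.
    """

    simulate: bool = True
    seed: int = 0
    n_samples: int = 6
    genome_path: str | None = None
    features_path: str | None = None
    table_path: str | None = None
    taxonomy_path: str | None = None
    sam_path: str | None = None
    fwd_primer: str = str(PRIMER_341F.seq)
    rev_primer: str = str(PRIMER_805R.seq)
    scan: ScanParams = field(default_factory=ScanParams)
    min_product_len: int = 100
    max_product_len: int = 600
    identity_min: float = 0.95
    coverage_min: float = 0.90
    cluster_tolerance: int = 5
    consensus_window: int = 32
    include_freq: float = 0.25
    drop_freq: float = 0.10
    min_coverage: float = 0.50
    design: DesignParams = field(default_factory=DesignParams)
    filter: FilterParams = field(default_factory=FilterParams)
    rarefaction_step: int = 100
    slope_threshold: float = 1e-4
    sim: SimConfig = field(default_factory=SimConfig)

    def __post_init__(self) -> None:
        if not self.simulate:
            if self.genome_path is None:
                raise ValueError("genome_path is required when simulate is false")
            for name in ("genome_path", "features_path", "table_path",
                         "taxonomy_path", "sam_path"):
                p = getattr(self, name)
                if p is not None and not Path(p).exists():
                    raise ValueError(f"{name} {p!r} does not exist")
        # every run is seeded; the simulator seed follows the run seed
        from dataclasses import replace as _replace

        self.sim = _replace(self.sim, seed=self.seed)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(asdict(self)), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key, sub in (("scan", ScanParams), ("design", DesignParams),
                         ("filter", FilterParams), ("sim", SimConfig)):
            if key in raw and isinstance(raw[key], dict):
                if key == "sim" and "loci" in raw[key]:
                    from .synthetic_data import PlantedLocus

                    raw[key]["loci"] = tuple(
                        PlantedLocus(**{**d, "fwd_mismatch_offsets": tuple(d.get("fwd_mismatch_offsets", (7, 12))),
                                        "rev_mismatch_offsets": tuple(d.get("rev_mismatch_offsets", (8, 14)))})
                        for d in raw[key]["loci"]
                    )
                raw[key] = sub(**raw[key])
        return cls(**raw)


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute every stage and return the run manifest (also written to
    ``manifest.json``).  A stage failure leaves partial outputs plus a
    ``FAILED`` marker naming the stage."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": asdict(config),
        "stages": {},
    }
    config.to_yaml(out / "effective_config.yaml")
    try:
        result = _run_stages(config, out, manifest)
    except Exception as exc:
        stage = exc.stage if isinstance(exc, PipelineError) else "unknown"
        (out / "FAILED").write_text(f"{stage}: {exc}\n")
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        raise
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return result


def _stage(manifest: dict, name: str, **counts) -> None:
    manifest["stages"][name] = counts
    logger.info("stage %s: %s", name, counts)


def _run_stages(config: RunConfig, out: Path, manifest: dict) -> dict:
    rng = np.random.default_rng(config.seed)
    fwd = Oligo("341F" if config.fwd_primer == str(PRIMER_341F.seq) else "fwd",
                NucSequence(config.fwd_primer), OligoRole.forward_primer)
    rev = Oligo("805R" if config.rev_primer == str(PRIMER_805R.seq) else "rev",
                NucSequence(config.rev_primer), OligoRole.reverse_primer)

    # ---- inputs -----------------------------------------------------
    stage = "inputs"
    try:
        if config.simulate:
            genome, truths = make_host_genome(config.sim, rng)
            community, abund = make_16s_community(config.sim, rng)
            kitome, _ = make_16s_community(
                config.sim, rng, n_templates=config.sim.n_kitome, prefix="kit")
            samples = {}
            for i in range(config.n_samples):
                factor = float(np.exp(rng.normal(0.0, 1.0)))
                samples[f"S{i + 1:02d}"] = simulate_pcr_reads(
                    truths, community, abund, config.sim, rng,
                    kitome=kitome, host_copy_factor=factor)
            templates = {f"host_{t.chrom}_{t.product_start}": str(t.amplicon_seq)
                         for t in truths}
            templates.update(community)
            templates.update(kitome)
            table, truth_host_ids = make_feature_tables(samples, templates)
            features = {fid: templates[fid] for fid in table.feature_ids}
            write_fasta(genome, out / "genome.fa")
            write_fasta(features, out / "features.fa")
            write_feature_table(table.counts, out / "table.tsv")
            table.taxonomy.to_csv(out / "taxonomy.tsv", sep="\t", index_label="feature_id")
            first = next(iter(samples.values()))
            write_fastq(first.reads, out / "reads_sample1.fastq")
            truth_bed = out / "planted_loci.bed"
            with open(truth_bed, "w") as fh:
                for t in truths:
                    fh.write(f"{t.chrom}\t{t.product_start}\t{t.product_end}"
                             f"\tplanted_locus\t0\t+\n")
            _stage(manifest, stage, loci=len(truths), taxa=len(community),
                   kitome=len(kitome), samples=len(samples),
                   features=len(table.feature_ids))
        else:
            genome = {k: str(v) for k, v in read_fasta(config.genome_path).items()}
            features = {}
            table = None
            if config.features_path:
                features = {k: str(v) for k, v in read_fasta(config.features_path).items()}
            if config.table_path:
                counts = read_feature_table(config.table_path)
                taxonomy = read_taxonomy(config.taxonomy_path) if config.taxonomy_path else None
                table = FeatureTable(counts=counts, taxonomy=taxonomy)
            _stage(manifest, stage, chromosomes=len(genome),
                   features=len(features))
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # ---- scan -------------------------------------------------------
    stage = "scan"
    try:
        fwd_sites = scan_priming_sites(genome, fwd, config.scan)
        rev_sites = scan_priming_sites(genome, rev, config.scan)
        sites = sorted(fwd_sites + rev_sites,
                       key=lambda s: (s.chrom, s.start, s.strand))
        write_sites_bed(sites, out / "priming_sites.bed")
        sites_to_frame(sites).to_csv(out / "priming_sites.tsv", sep="\t", index=False)
        _stage(manifest, stage, fwd_sites=len(fwd_sites), rev_sites=len(rev_sites))
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # ---- predict ----------------------------------------------------
    stage = "predict"
    try:
        amplicons = predict_amplicons(fwd_sites, rev_sites,
                                      config.min_product_len,
                                      config.max_product_len, genome)
        amplicons_to_frame(amplicons).to_csv(out / "predicted_amplicons.tsv",
                                             sep="\t", index=False)
        write_fasta({f"amplicon_{i + 1}": str(a.insert_seq)
                     for i, a in enumerate(amplicons)},
                    out / "amplicon_inserts.fa")
        _stage(manifest, stage, amplicons=len(amplicons))
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # ---- classify ---------------------------------------------------
    stage = "classify"
    classified = []
    try:
        if table is not None:
            if config.sam_path:
                classified = ingest_sam(config.sam_path, table.counts)
            else:
                classified = classify_features(
                    features, table.counts, genome,
                    identity_min=config.identity_min,
                    coverage_min=config.coverage_min)
            rows = [{"feature_id": f.feature_id, "label": f.label,
                     "chrom": f.best_hit.chrom if f.best_hit else "",
                     "pos_1based": f.best_hit.start + 1 if f.best_hit else "",
                     "strand": f.best_hit.strand if f.best_hit else "",
                     "read_weight": f.read_weight}
                    for f in classified]
            pd.DataFrame(rows).to_csv(out / "classified_features.tsv",
                                      sep="\t", index=False)
            chromosome_report(classified).to_csv(out / "chromosome_report.tsv",
                                                 sep="\t", index=False)
        n_host = sum(f.label == "host_offtarget" for f in classified)
        _stage(manifest, stage, features=len(classified), host_offtarget=n_host)
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # ---- cluster ----------------------------------------------------
    stage = "cluster"
    clusters = []
    try:
        if any(f.label == "host_offtarget" for f in classified):
            clusters = cluster_positions(classified, config.cluster_tolerance)
            pd.DataFrame(
                [{"chrom": c.chrom, "strand": c.strand,
                  "mode_pos_1based": c.mode_start,
                  "total_reads": c.total_reads, "n_features": c.n_features}
                 for c in clusters]
            ).to_csv(out / "position_clusters.tsv", sep="\t", index=False)
        _stage(manifest, stage, clusters=len(clusters))
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # ---- consensus --------------------------------------------------
    stage = "consensus"
    motif = None
    try:
        host_seqs = [features[f.feature_id] for f in classified
                     if f.label == "host_offtarget"]
        trimmed = [s[len(str(fwd.seq)):] for s in host_seqs]
        trimmed = [s for s in trimmed if len(s) >= config.consensus_window]
        if trimmed:
            block = anchor_align(trimmed, "five_prime", config.consensus_window)
            motif = call_iupac_consensus(
                build_pfm(block), config.include_freq, config.drop_freq,
                config.min_coverage)
            freqs = motif.column_frequencies()
            pd.DataFrame(freqs.T, columns=list("ACGT")).to_csv(
                out / "consensus_logo.tsv", sep="\t", index_label="column")
            pd.DataFrame(motif.pfm.T, columns=list("ACGT")).to_csv(
                out / "consensus_pfm.tsv", sep="\t", index_label="column")
            write_fasta({"consensus_full": str(motif.iupac_full),
                         "consensus_reduced": str(motif.iupac_reduced)},
                        out / "consensus.fa")
        _stage(manifest, stage, sequences=len(trimmed),
               consensus_reduced=str(motif.iupac_reduced) if motif else "")
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # ---- design-inhibitor -------------------------------------------
    stage = "design-inhibitor"
    design = None
    try:
        if motif is not None:
            microbial_refs = {f.feature_id: features[f.feature_id]
                              for f in classified if f.label == "non_host"}
            design = design_inhibitor(motif, [fwd, rev], config.design,
                                      microbial_refs=microbial_refs)
            write_fasta({f"{design.oligo.name} /3SpC3/": str(design.oligo.seq)},
                        out / "inhibitor.fa")
            pd.DataFrame([{
                "oligo": str(design.oligo.seq),
                "length": len(design.oligo.seq),
                "three_prime_mod": design.oligo.three_prime_mod.value,
                "tm_C": round(design.tm, 2),
                "delta_tm_C": round(design.delta_tm, 2),
                "hairpin": design.hairpin.has_hairpin,
                "cross_hits": len(design.cross_hits),
                "accepted": design.accepted,
            }]).to_csv(out / "inhibitor_design.tsv", sep="\t", index=False)
        _stage(manifest, stage,
               accepted=bool(design.accepted) if design else False)
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # ---- bias -------------------------------------------------------
    stage = "bias"
    try:
        bias_outputs = {}
        if table is not None:
            host_ids = {f.feature_id for f in classified
                        if f.label == "host_offtarget"}
            comparison = compare_with_without(table, host_ids)
            comparison.to_csv(out / "abundance_comparison.tsv", sep="\t")
            host_tab, microb_tab = table.partition(host_ids)
            filt = filter_features(microb_tab, config.filter)
            filt.log.to_csv(out / "filter_log.tsv", sep="\t", index=False)
            write_feature_table(filt.table.counts, out / "table_decontaminated.tsv")
            write_feature_table(table.counts, out / "table_with_offtargets.tsv")
            genus = filt.table.genus_table()
            raref = [rarefaction_curve(genus[c], config.rarefaction_step,
                                       config.slope_threshold, sample_id=c)
                     for c in genus.columns]
            pd.DataFrame(
                [{"sample": r.sample_id, "final_slope": r.final_slope,
                  "saturated": r.saturated, "evaluable": r.evaluable}
                 for r in raref]
            ).to_csv(out / "rarefaction.tsv", sep="\t", index=False)
            if genus.shape[1] >= 2:
                for tag, tab in (("with", table), ("without", filt.table)):
                    ordn = hellinger_pcoa(tab, k=2)
                    ordn.coordinates.to_csv(out / f"pcoa_{tag}_offtargets.tsv", sep="\t")
                    bias_outputs[f"pcoa_{tag}"] = ordn
            bias_outputs.update(comparison=comparison, filtered=filt, rarefaction=raref)
        _stage(manifest, stage, n_host=len(host_ids) if table is not None else 0)
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    return {
        "manifest": manifest,
        "sites": sites,
        "amplicons": amplicons,
        "classified": classified,
        "clusters": clusters,
        "consensus": motif,
        "inhibitor": design,
        "bias": bias_outputs,
    }
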