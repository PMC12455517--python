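"""Readers and writers for the standard formats the pipeline touches.

FASTA/FASTQ go through Biopython (gzip transparently accepted on read),
tables through pandas TSV, priming sites additionally as BED6.  All
human-facing tables carry 1-based coordinates next to the 0-based
half-open internal convention; BED stays 0-based half-open per the BED
standard.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, TextIO

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .mispriming import PredictedAmplicon, PrimingSite
from .seqcore import NucSequence

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "write_sites_bed",
    "sites_to_frame",
    "amplicons_to_frame",
    "read_feature_table",
    "write_feature_table",
    "read_taxonomy",
]


def _open_text(path: str | Path, mode: str = "rt") -> TextIO:
    p = Path(path)
    if p.suffix == ".gz":
        return gzip.open(p, mode)
    return open(p, mode)


def read_fasta(path: str | Path) -> dict[str, NucSequence]:
    """Read a (possibly gzipped, multi-line) FASTA into an id -> sequence
    map, validating residues and id uniqueness."""
    out: dict[str, NucSequence] = {}
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in out:
                raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
            try:
                out[rec.id] = NucSequence(str(rec.seq))
            except ValueError as exc:
                raise ValueError(f"record {rec.id!r}: {exc}") from exc
    return out


def write_fasta(seqs: dict[str, str], path: str | Path, wrap: int = 80) -> None:
    records = [SeqRecord(Seq(str(s)), id=name, description="")
               for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(records)


def read_fastq(path: str | Path) -> list[tuple[str, str, str]]:
    """Read Phred+33 FASTQ (gzip accepted) into (id, seq, qual) tuples."""
    out = []
    with _open_text(path) as fh:
        for i, rec in enumerate(SeqIO.parse(fh, "fastq")):
            quals = rec.letter_annotations["phred_quality"]
            if len(quals) != len(rec.seq):
                raise ValueError(f"record {i}: sequence/quality length mismatch")
            qual = "".join(chr(q + 33) for q in quals)
            out.append((rec.id, str(rec.seq), qual))
    return out


def write_fastq(reads: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq, qual in reads:
            if len(seq) != len(qual):
                raise ValueError(f"read {name!r}: sequence/quality length mismatch")
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def write_sites_bed(sites: Iterable[PrimingSite], path: str | Path) -> None:
    """BED6: name = primer, score = mismatch count (0-based half-open)."""
    with open(path, "w") as fh:
        for s in sites:
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.primer_name}"
                     f"\t{s.n_mismatches}\t{s.strand}\n")


def sites_to_frame(sites: Iterable[PrimingSite]) -> pd.DataFrame:
    """Priming sites as a table with both coordinate conventions."""
    return pd.DataFrame(
        [
            {
                "chrom": s.chrom,
                "start_0based": s.start,
                "end": s.end,
                "pos_1based": s.pos_1based,
                "strand": s.strand,
                "primer": s.primer_name,
                "n_mismatches": s.n_mismatches,
                "mismatch_offsets_3p": ",".join(map(str, s.mismatch_offsets)),
            }
            for s in sites
        ],
        columns=["chrom", "start_0based", "end", "pos_1based", "strand",
                 "primer", "n_mismatches", "mismatch_offsets_3p"],
    )


def amplicons_to_frame(amplicons: Iterable[PredictedAmplicon]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": a.chrom,
                "product_start_0based": a.product_start,
                "product_end": a.product_end,
                "product_start_1based": a.product_start + 1,
                "product_len": a.product_len,
                "fwd_primer": a.fwd_site.primer_name,
                "fwd_start_0based": a.fwd_site.start,
                "fwd_strand": a.fwd_site.strand,
                "rev_primer": a.rev_site.primer_name,
                "rev_start_0based": a.rev_site.start,
                "rev_strand": a.rev_site.strand,
                "insert_seq": str(a.insert_seq),
            }
            for a in amplicons
        ],
        columns=["chrom", "product_start_0based", "product_end",
                 "product_start_1based", "product_len", "fwd_primer",
                 "fwd_start_0based", "fwd_strand", "rev_primer",
                 "rev_start_0based", "rev_strand", "insert_seq"],
    )


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Feature x sample TSV (header row of sample ids, first column ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(int)


def write_feature_table(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="feature_id")


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    """Taxonomy TSV: feature_id, phylum, genus, organelle (bool)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "organelle" in df.columns:
        df["organelle"] = df["organelle"].astype(bool)
    return df
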