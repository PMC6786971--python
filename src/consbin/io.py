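"""Readers and writers for all on-disk formats.

Formats are the plain-text de-facto standards of the binning ecosystem:

* assembly FASTA (only record ids and lengths are needed; sequences matter
  solely for bin export);
* contigs2bin TSV — two tab-separated columns ``contig-id TAB bin-id``, one
  file per binning tool, ``#`` comment lines tolerated, no header required;
* SCG annotation TSV — ``contig  gene  family  domain  span-fraction``;
* reference map TSVs for evaluation — ``contig  genome  overlap-bp`` plus a
  genome table ``genome  length  strain-class  circular``;
* result summary and final contigs2bin outputs, optionally per-bin FASTA.

All TSV readers accept plain or gzip-compressed files.  Writers are
deterministic: rows sorted by (bin uid, contig id), scores printed with six
decimals.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from .core import BinSet, CandidateBin, Contig, DOMAINS, fasta_record_id
from .evaluation import ReferenceMap
from .scg import SCGAnnotation
from .scoring import BinScore

__all__ = [
    "SummaryRecord",
    "read_contigs2bin",
    "read_scg_table",
    "read_fasta_lengths",
    "read_reference_map",
    "write_outputs",
    "write_scg_table",
    "write_contigs2bin",
    "write_reference_map",
]


def _open_text(path):
    path = os.fspath(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


@dataclass(frozen=True)
class SummaryRecord:
    """One row of the final summary table."""

    bin: str
    binner: str
    score: float
    uscg: int
    dscg: int
    total_scg: int
    domain: str
    size_bp: int
    n50: int
    n_contigs: int

    def __post_init__(self) -> None:
        if self.score > 1.0:
            raise ValueError(f"bin score cannot exceed 1, got {self.score}")
        if not (self.dscg <= self.uscg <= self.total_scg):
            raise ValueError("need dSCG <= uSCG <= totalSCG")


SUMMARY_COLUMNS = [
    "bin", "binner", "score", "uSCG", "dSCG", "totalSCG",
    "domain", "size_bp", "n50", "n_contigs",
]


def read_contigs2bin(path, label: str) -> BinSet:
    """Parse one binner's contig -> bin table into a BinSet."""
    bins: dict[str, set[str]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, got {len(fields)}"
                )
            contig, bin_id = (f.strip() for f in fields)
            if not contig or not bin_id:
                raise ValueError(f"{path}:{lineno}: empty contig or bin id")
            bins.setdefault(bin_id, set()).add(contig)
    return BinSet(label=label, bins=bins)  # BinSet validates one-bin-per-contig


def read_scg_table(path) -> SCGAnnotation:
    """Read an SCG annotation table of accepted gene calls.

    Columns: contig-id, gene-id, scg-family-id, domain, span-fraction.
    The table is the output of the gene-prediction adapter, i.e. the span
    rule has already been applied; rows here are taken as accepted calls.
    An empty file is valid and yields an empty annotation.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["contig", "gene", "family", "domain", "span"],
            dtype={"contig": str, "gene": str, "family": str, "domain": str, "span": float},
        )
    except pd.errors.EmptyDataError:
        return SCGAnnotation()
    bad_domain = set(df["domain"]) - set(DOMAINS)
    if bad_domain:
        raise ValueError(f"{path}: unknown domain value(s) {sorted(bad_domain)}")
    if ((df["span"] < 0) | (df["span"] > 1)).any():
        raise ValueError(f"{path}: span fraction outside [0, 1]")
    if df.duplicated(subset=["contig", "gene"]).any():
        dup = df[df.duplicated(subset=["contig", "gene"])].iloc[0]
        raise ValueError(f"{path}: duplicate (contig, gene) entry ({dup['contig']}, {dup['gene']})")
    ann = SCGAnnotation()
    for row in df.itertuples(index=False):
        ann.add(row.contig, row.family, row.domain, row.gene)
    return ann


def write_scg_table(ann: SCGAnnotation, path, span: float = 1.0) -> None:
    """Write an annotation back out as an SCG TSV (span column constant)."""
    rows = []
    for contig in sorted(ann.hits):
        for family, domain, gene in sorted(ann.hits[contig]):
            rows.append((contig, gene, family, domain, f"{span:.2f}"))
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(map(str, row)) + "\n")


def read_fasta_lengths(path) -> list[Contig]:
    """Contig ids and lengths from an assembly FASTA (plain or gzipped)."""
    contigs: list[Contig] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for record in SeqIO.parse(fh, "fasta"):
            cid = fasta_record_id(record.id)
            if cid in seen:
                raise ValueError(f"{path}: duplicate contig id {cid!r}")
            if len(record.seq) == 0:
                raise ValueError(f"{path}: zero-length record {cid!r}")
            seen.add(cid)
            contigs.append(Contig(id=cid, length=len(record.seq)))
    return contigs


def read_reference_map(map_path, genome_path) -> ReferenceMap:
    """Load the contig -> reference-genome map used by the evaluation metrics.

    ``map_path``: TSV contig-id, genome-id, overlap-bp.
    ``genome_path``: TSV genome-id, length-bp, strain-class
    (unique_strain | common_strain), circular flag (0/1).
    """
    cmap = pd.read_csv(map_path, sep="\t", comment="#", header=None,
                       names=["contig", "genome", "overlap"],
                       dtype={"contig": str, "genome": str, "overlap": int})
    gtab = pd.read_csv(genome_path, sep="\t", comment="#", header=None,
                       names=["genome", "length", "strain_class", "circular"],
                       dtype={"genome": str, "length": int, "strain_class": str})
    return ReferenceMap(
        contig_to_genome={r.contig: (r.genome, int(r.overlap)) for r in cmap.itertuples()},
        genome_lengths={r.genome: int(r.length) for r in gtab.itertuples()},
        strain_class={r.genome: r.strain_class for r in gtab.itertuples()},
        circular={r.genome: bool(int(r.circular)) for r in gtab.itertuples()},
    )


def write_reference_map(ref: ReferenceMap, map_path, genome_path) -> None:
    with open(map_path, "w") as fh:
        for contig in sorted(ref.contig_to_genome):
            genome, overlap = ref.contig_to_genome[contig]
            fh.write(f"{contig}\t{genome}\t{overlap}\n")
    with open(genome_path, "w") as fh:
        for genome in sorted(ref.genome_lengths):
            fh.write(
                f"{genome}\t{ref.genome_lengths[genome]}\t"
                f"{ref.strain_class.get(genome, 'unique_strain')}\t"
                f"{int(ref.circular.get(genome, False))}\n"
            )


def write_contigs2bin(bins: Mapping[str, Iterable[str]], path) -> None:
    """Write a contig TAB bin table, rows sorted by (bin id, contig id)."""
    with open(path, "w") as fh:
        for bin_id in sorted(bins):
            for contig in sorted(bins[bin_id]):
                fh.write(f"{contig}\t{bin_id}\n")


def write_outputs(
    final: list[tuple[CandidateBin, BinScore]],
    prefix,
    sequences: Mapping[str, str] | None = None,
    write_bins: bool = False,
) -> dict[str, Path]:
    """Write the final bin set: summary TSV, contigs2bin TSV, optional FASTAs.

    ``sequences`` (contig id -> sequence string) is only needed when
    ``write_bins`` is set; the core pipeline runs on lengths alone.
    """
    prefix = Path(prefix)
    if prefix.parent and not prefix.parent.exists():
        prefix.parent.mkdir(parents=True, exist_ok=True)

    records = []
    for bin_, bs in final:
        records.append(SummaryRecord(
            bin=bin_.uid, binner=bin_.origin, score=bs.score,
            uscg=bs.counts.uscg, dscg=bs.counts.dscg, total_scg=bs.counts.total,
            domain=bs.domain, size_bp=bin_.size_bp, n50=bin_.n50,
            n_contigs=len(bin_.contigs),
        ))
    records.sort(key=lambda r: r.bin)

    summary_path = Path(f"{prefix}_summary.tsv")
    with open(summary_path, "w") as fh:
        fh.write("\t".join(SUMMARY_COLUMNS) + "\n")
        for r in records:
            fh.write(
                f"{r.bin}\t{r.binner}\t{r.score:.6f}\t{r.uscg}\t{r.dscg}\t"
                f"{r.total_scg}\t{r.domain}\t{r.size_bp}\t{r.n50}\t{r.n_contigs}\n"
            )

    c2b_path = Path(f"{prefix}_contigs2bin.tsv")
    write_contigs2bin({b.uid: b.contigs for b, _ in final}, c2b_path)

    out = {"summary": summary_path, "contigs2bin": c2b_path}
    if write_bins:
        if sequences is None:
            raise ValueError("write_bins requires contig sequences")
        bin_dir = Path(f"{prefix}_bins")
        bin_dir.mkdir(parents=True, exist_ok=True)
        for bin_, _ in final:
            fasta = bin_dir / f"{bin_.uid}.fasta"
            with open(fasta, "w") as fh:
                for cid in sorted(bin_.contigs):
                    fh.write(f">{cid}\n{sequences[cid]}\n")
        out["bin_dir"] = bin_dir
    return out
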