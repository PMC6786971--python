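"""Bin-accuracy metrics against a reference genome map, and parameter search.

Given a ground-truth assignment of contigs to reference genomes, each bin is
matched to the genome contributing the largest fraction of its nucleotides;
precision is the matched fraction of the bin, recall the covered fraction of
that genome, and F1 their harmonic mean:

    P = len(B ∩ G) / len(B)      R = len(B ∩ G) / len(G)
    F1 = 2 P R / (P + R)         (0 when both are 0)

Bins whose best match is a circular element (plasmid, phage) are excluded
from summaries, since the method targets bacterial and archaeal genomes.
Counts are reported per strain stratum: genomes labelled ``unique_strain``
(< 95% ANI to every other reference) vs ``common_strain`` (>= 95% ANI to
some other reference); the labels are consumed as input, ANI itself is
never computed here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core import CandidateBin, ReferenceSCGSet, ScoringParams
from .scg import SCGAnnotation
from .selection import dereplicate_select

__all__ = [
    "ReferenceMap",
    "BinEvaluation",
    "eval_bin",
    "summarize",
    "classify_quality",
    "recovery_fraction",
    "grid_search",
]

STRAIN_CLASSES = ("unique_strain", "common_strain")


@dataclass
class ReferenceMap:
    """Ground truth for evaluation: where each contig really came from.

    ``contig_to_genome`` maps a contig to its source genome and the number
    of its nucleotides attributable to that genome (at most the contig
    length).  Genome lengths, strain-class labels and circular-element
    flags are per genome.
    """

    contig_to_genome: dict[str, tuple[str, int]]
    genome_lengths: dict[str, int]
    strain_class: dict[str, str] = field(default_factory=dict)
    circular: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for genome, length in self.genome_lengths.items():
            if length <= 0:
                raise ValueError(f"genome {genome!r}: length must be > 0")
        for contig, (genome, overlap) in self.contig_to_genome.items():
            if genome not in self.genome_lengths:
                raise ValueError(f"contig {contig!r} maps to unknown genome {genome!r}")
            if overlap < 0:
                raise ValueError(f"contig {contig!r}: negative overlap")

    @property
    def genomes(self) -> list[str]:
        return sorted(self.genome_lengths)

    def n_genomes(self, include_circular: bool = False) -> int:
        if include_circular:
            return len(self.genome_lengths)
        return sum(1 for g in self.genome_lengths if not self.circular.get(g, False))


@dataclass(frozen=True)
class BinEvaluation:
    """Accuracy of one bin: best-matching genome, precision, recall, F1."""

    uid: str
    genome: str | None  # None when no nucleotide of the bin maps anywhere
    precision: float
    recall: float
    f1: float


def _f1(p: float, r: float) -> float:
    return 0.0 if p + r == 0 else 2 * p * r / (p + r)


def eval_bin(bin_: CandidateBin, ref: ReferenceMap) -> BinEvaluation:
    """Match a bin to its best reference genome and score it.

    The best genome maximises the bin's mapped-nucleotide fraction;
    argmax ties go to the larger genome, then the lexicographically
    smallest genome id.  A bin with no mapped nucleotides gets
    P = R = F1 = 0 and no genome.
    """
    if not bin_.contigs:
        raise ValueError(f"bin {bin_.uid!r} is empty")
    overlap: dict[str, int] = {}
    for cid in bin_.contigs:
        hit = ref.contig_to_genome.get(cid)
        if hit is not None:
            genome, bp = hit
            overlap[genome] = overlap.get(genome, 0) + bp
    if not overlap or all(v == 0 for v in overlap.values()):
        return BinEvaluation(uid=bin_.uid, genome=None, precision=0.0, recall=0.0, f1=0.0)
    best = min(overlap, key=lambda g: (-overlap[g], -ref.genome_lengths[g], g))
    p = overlap[best] / bin_.size_bp
    r = overlap[best] / ref.genome_lengths[best]
    return BinEvaluation(uid=bin_.uid, genome=best, precision=p, recall=r, f1=_f1(p, r))


def summarize(
    results: Iterable[BinEvaluation],
    ref: ReferenceMap,
    f1_grid: Sequence[float] = (0.5, 0.6, 0.7, 0.8, 0.9),
) -> pd.DataFrame:
    """Stratified counts of bins above each F1 threshold, plus median F1.

    Bins whose best genome is a circular element are dropped first.  Rows:
    one per (stratum, threshold), strata being ``all`` plus each strain
    class present; unmapped bins (no genome) count only in ``all``.
    """
    kept = [r for r in results if r.genome is None or not ref.circular.get(r.genome, False)]
    strata: dict[str, list[BinEvaluation]] = {"all": kept}
    for r in kept:
        if r.genome is not None:
            cls = ref.strain_class.get(r.genome)
            if cls:
                strata.setdefault(cls, []).append(r)
    rows = []
    for stratum in ["all"] + [c for c in STRAIN_CLASSES if c in strata]:
        members = strata.get(stratum, [])
        if not members:
            continue
        f1s = sorted(r.f1 for r in members)
        median = float(pd.Series(f1s).median())
        for thr in f1_grid:
            rows.append({
                "stratum": stratum,
                "f1_threshold": thr,
                "n_bins_above": sum(1 for x in f1s if x > thr),
                "n_bins": len(members),
                "median_f1": median,
            })
    return pd.DataFrame(rows, columns=["stratum", "f1_threshold", "n_bins_above", "n_bins", "median_f1"])


def classify_quality(completeness: float, contamination: float) -> str:
    """Genome quality tier from completeness/contamination percentages.

    near_complete: > 90% complete and < 5% contamination;
    draft: 70-90% complete and < 5% contamination; otherwise none.
    """
    for name, value in (("completeness", completeness), ("contamination", contamination)):
        if not 0.0 <= value <= 100.0:
            raise ValueError(f"{name} must be a percentage in [0, 100], got {value}")
    if contamination < 5.0:
        if completeness > 90.0:
            return "near_complete"
        if 70.0 <= completeness <= 90.0:
            return "draft"
    return "none"


def recovery_fraction(n_bins: int, n_otu_clusters: int) -> float:
    """Percent of expected species recovered as draft genomes, 1 decimal.

    The expected species count is the number of marker-gene OTU clusters in
    the assembly (e.g. ribosomal protein S3 clustered at 99% identity);
    the fraction is bins / clusters, rounded half-up to one decimal.
    """
    if n_otu_clusters <= 0:
        raise ValueError("number of OTU clusters must be > 0")
    if n_bins < 0:
        raise ValueError("number of bins must be >= 0")
    pct = Decimal(100 * n_bins) / Decimal(n_otu_clusters)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def grid_search(
    candidates: list[CandidateBin],
    ann: SCGAnnotation,
    refs: Mapping[str, ReferenceSCGSet],
    assembly: Mapping[str, int],
    b_values: Sequence[float],
    c_values: Sequence[float],
    t_values: Sequence[float],
    eval_ref: ReferenceMap,
    f1_quality: float = 0.6,
) -> pd.DataFrame:
    """Grid search over the scoring weights b, c and the threshold t.

    One row per (b, c, t): the number of final bins, the number of quality
    bins (ground-truth F1 > ``f1_quality``, circular matches excluded),
    and the mean precision/recall over evaluated final bins.  The
    ``objective`` column is the sum of the quality-bin fraction (quality
    bins / non-circular reference genomes), mean precision and mean
    recall; rows attaining its maximum are flagged ``is_optimum``.

    Because the threshold only gates admission into the final set — it
    never changes extraction order or contig claiming — each (b, c) pair
    needs a single selection run at t = 0, from which every t row is
    obtained by filtering on score > t.  The result is identical to
    running the full loop per (b, c, t).
    """
    if not (b_values and c_values and t_values):
        raise ValueError("parameter grids must be non-empty")
    n_ref = max(eval_ref.n_genomes(include_circular=False), 1)
    rows = []
    for b in b_values:
        for c in c_values:
            base = dereplicate_select(
                candidates, ann, refs, ScoringParams(b=b, c=c, t=0.0), assembly=assembly
            )
            evals = []
            for bin_, bs in base.final:
                ev = eval_bin(bin_, eval_ref)
                circ = ev.genome is not None and eval_ref.circular.get(ev.genome, False)
                evals.append((bs.score, ev, circ))
            for t in t_values:
                sel = [(s, ev, circ) for s, ev, circ in evals if s > t]
                kept = [(ev.precision, ev.recall, ev.f1) for s, ev, circ in sel if not circ]
                n_quality = sum(1 for _, _, f1 in kept if f1 > f1_quality)
                mean_p = sum(p for p, _, _ in kept) / len(kept) if kept else math.nan
                mean_r = sum(r for _, r, _ in kept) / len(kept) if kept else math.nan
                objective = (
                    n_quality / n_ref + mean_p + mean_r if kept else -math.inf
                )
                rows.append({
                    "b": b, "c": c, "t": t,
                    "n_final": len(sel),
                    "n_quality_bins": n_quality,
                    "mean_precision": mean_p,
                    "mean_recall": mean_r,
                    "objective": objective,
                })
    df = pd.DataFrame(rows)
    best = df["objective"].max()
    df["is_optimum"] = df["objective"] == best
    return df
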