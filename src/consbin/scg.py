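"""Single-copy-gene (SCG) presence calls and per-bin tallies.

Completeness and contamination of a candidate bin are estimated from single
copy genes: families expected exactly once per genome.  A gene predicted on
a contig is *called present* for an SCG family when its best homology hit
satisfies the span rule (the aligned query covers at least half of the
alignment with the best database hit); each gene contributes at most one
copy to exactly one family, so one gene can never inflate the total copy
count.

External gene prediction / homology search adapter contract
-----------------------------------------------------------
The package never invokes external binaries.  A conforming adapter runs:

1. gene calling on the assembly in metagenome mode, with gene models not
   built across ambiguous nucleotides (e.g. ``prodigal -p meta -m``);
2. a seed search of the predicted proteins against the SCG family database
   at e-value <= 1e-2 to collect candidate SCGs;
3. a confirmation search of those candidates against the full database at
   e-value <= 1e-5.

Its output is expressed as :class:`RawHit` rows (or the equivalent TSV of
:mod:`consbin.io`), which :func:`classify_hits` turns into presence calls.
Any search engine with e-values and alignment spans satisfies the contract.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .core import DOMAINS, CandidateBin, ReferenceSCGSet

__all__ = ["RawHit", "SCGAnnotation", "SCGCounts", "classify_hits", "tally_bin_scgs"]


@dataclass(frozen=True)
class RawHit:
    """One homology hit of a predicted gene against an SCG family."""

    gene_id: str
    contig_id: str
    family: str
    domain: str
    evalue: float
    span_fraction: float  # aligned query span / alignment length with best db hit

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise ValueError(f"unknown domain {self.domain!r}")
        if not 0.0 <= self.span_fraction <= 1.0:
            raise ValueError(f"span fraction must be in [0, 1], got {self.span_fraction}")
        if self.evalue <= 0:
            raise ValueError("e-value must be > 0")


@dataclass
class SCGAnnotation:
    """Accepted SCG calls, keyed by contig: contig -> [(family, domain, gene_id)]."""

    hits: dict[str, list[tuple[str, str, str]]] = field(default_factory=dict)

    def add(self, contig_id: str, family: str, domain: str, gene_id: str) -> None:
        self.hits.setdefault(contig_id, []).append((family, domain, gene_id))

    def family_counts(self, contigs: Iterable[str], domain: str, families: frozenset[str]) -> Counter:
        """Copy count per reference family over a set of contigs, one domain."""
        counts: Counter = Counter()
        for cid in contigs:
            for family, dom, _gene in self.hits.get(cid, ()):
                if dom == domain and family in families:
                    counts[family] += 1
        return counts

    @property
    def n_genes(self) -> int:
        return sum(len(v) for v in self.hits.values())


def classify_hits(hits: Iterable[RawHit], min_span: float = 0.5) -> SCGAnnotation:
    """Turn raw homology hits into SCG presence calls.

    A gene is called present for a family iff its best hit passes the span
    rule (span fraction >= ``min_span``, inclusive — "at least 50%").  When a
    gene hits several families, the best e-value wins and the gene is
    assigned to that family only; e-value ties are broken by higher span,
    then lexicographically smallest family id.  Idempotent and independent
    of input order.
    """
    if not 0.0 < min_span <= 1.0:
        raise ValueError(f"min_span must be in (0, 1], got {min_span}")
    best: dict[str, RawHit] = {}
    for hit in hits:
        if hit.span_fraction < min_span:
            continue
        prev = best.get(hit.gene_id)
        if prev is None or _hit_rank(hit) < _hit_rank(prev):
            best[hit.gene_id] = hit
    ann = SCGAnnotation()
    for gene_id in sorted(best):
        hit = best[gene_id]
        ann.add(hit.contig_id, hit.family, hit.domain, gene_id)
    return ann


def _hit_rank(hit: RawHit) -> tuple[float, float, str]:
    # lower is better: e-value asc, span desc, family id asc
    return (hit.evalue, -hit.span_fraction, hit.family)


@dataclass(frozen=True)
class SCGCounts:
    """Per-bin SCG tallies of one domain, the inputs to the scoring function.

    uscg  : distinct reference families present in the bin
    dscg  : families present in two or more copies
    total : total accepted gene copies across reference families (sigma-SCG)
    """

    domain: str
    uscg: int
    dscg: int
    total: int

    def __post_init__(self) -> None:
        if min(self.uscg, self.dscg, self.total) < 0:
            raise ValueError("SCG counts must be non-negative")
        if not (self.dscg <= self.uscg <= self.total):
            raise ValueError(
                f"inconsistent SCG counts: need dscg <= uscg <= total, "
                f"got ({self.dscg}, {self.uscg}, {self.total})"
            )


def tally_bin_scgs(
    bin_: CandidateBin | Iterable[str],
    ann: SCGAnnotation,
    ref: ReferenceSCGSet,
) -> SCGCounts:
    """Tally one bin's SCG copies against one domain's reference families.

    Only the bin's *current* contigs count, and only families in the
    domain's reference set; a bacterial family never enters the archaeal
    tally.
    """
    contigs = bin_.contigs if isinstance(bin_, CandidateBin) else bin_
    counts = ann.family_counts(contigs, ref.domain, ref.families)
    uscg = len(counts)
    dscg = sum(1 for n in counts.values() if n >= 2)
    total = sum(counts.values())
    return SCGCounts(domain=ref.domain, uscg=uscg, dscg=dscg, total=total)
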