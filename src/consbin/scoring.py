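"""The single-copy-gene bin scoring function.

A bin's score estimates completeness minus contamination from SCG tallies:

    S = uSCG/rSCG  -  b * dSCG/uSCG  -  c * (sigmaSCG - uSCG)/rSCG

where uSCG is the number of distinct reference families present, dSCG the
number of families present in two or more copies, sigmaSCG the total copy
count and rSCG the size of the domain's reference family set (51 bacterial,
38 archaeal by default).  The first term rewards completeness; the second
penalises duplicated families; the third penalises total surplus copies and
is what drives multi-genome "megabins" towards zero or negative scores.

Each bin is scored against both domain reference sets and the greater of
the two scores wins, which is how the method decides whether a bin looks
bacterial or archaeal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .core import CandidateBin, ReferenceSCGSet, ScoringParams
from .scg import SCGAnnotation, SCGCounts, tally_bin_scgs

__all__ = ["BinScore", "score_counts", "score_bin"]


@dataclass(frozen=True)
class BinScore:
    """Score of one bin: winning domain, its tallies, and both sub-scores."""

    score: float
    domain: str
    counts: SCGCounts
    sub_scores: Mapping[str, float]


def score_counts(counts: SCGCounts, ref: ReferenceSCGSet, params: ScoringParams) -> float:
    """Score one domain's tallies.

    With no unique SCGs the duplicate term is taken as 0 (its limiting
    value), so an SCG-free bin scores exactly 0 and a bin with only surplus
    copies is still penalised by the megabin term.
    """
    if counts.domain != ref.domain:
        raise ValueError(f"counts are {counts.domain!r} but reference set is {ref.domain!r}")
    rscg = ref.rscg
    completeness = counts.uscg / rscg
    duplicate = counts.dscg / counts.uscg if counts.uscg > 0 else 0.0
    megabin = (counts.total - counts.uscg) / rscg
    return completeness - params.b * duplicate - params.c * megabin


def score_bin(
    bin_: CandidateBin,
    ann: SCGAnnotation,
    refs: Mapping[str, ReferenceSCGSet],
    params: ScoringParams,
) -> BinScore:
    """Score a bin against all domain reference sets; the best domain wins.

    Score ties between domains go to the domain with more distinct SCG
    families present (the better-supported call), then to the
    lexicographically first domain name for determinism.
    """
    sub: dict[str, float] = {}
    tallies: dict[str, SCGCounts] = {}
    for domain in sorted(refs):
        tallies[domain] = tally_bin_scgs(bin_, ann, refs[domain])
        sub[domain] = score_counts(tallies[domain], refs[domain], params)
    winner = min(sub, key=lambda d: (-sub[d], -tallies[d].uscg, d))
    return BinScore(score=sub[winner], domain=winner, counts=tallies[winner], sub_scores=sub)
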