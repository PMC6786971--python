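"""Greedy dereplication-aggregation-selection of a non-redundant bin set.

Different binning tools reconstruct overlapping, partially redundant bins
from the same assembly.  The selection loop resolves that redundancy:

1. score every candidate bin (SCG scoring, domain max);
2. extract the highest-scoring candidate — ties go to the higher contig
   N50, then the larger bin in bp, then the lexicographically smallest uid;
3. stop when the best remaining score is not above zero;
4. the extracted bin enters the final set if its score exceeds the
   threshold ``t``; either way its contigs are deleted from every remaining
   candidate, emptied candidates are dropped, and every altered candidate
   is rescored (size and N50 included, since they feed future tie-breaks);
5. repeat until the pool is empty.

Because ``t`` only gates admission into the final set — extraction order
and contig claiming are the same for every ``t`` — raising the threshold
can only shrink the final set, never reorder it.  The optional
``release_subthreshold`` mode instead returns a sub-threshold bin's contigs
to the pool, sacrificing that property for higher contig usage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .core import CandidateBin, ReferenceSCGSet, ScoringParams, as_length_map
from .scg import SCGAnnotation
from .scoring import BinScore, score_bin

__all__ = ["SelectionResult", "IterationRecord", "select_next", "dereplicate_select"]


@dataclass(frozen=True)
class IterationRecord:
    """One iteration of the selection loop, for audit logging."""

    iteration: int
    extracted_uid: str
    score: float
    tie_break: str  # which criterion decided: score | n50 | size_bp | uid
    accepted: bool  # score > t, bin entered the final set
    altered: tuple[str, ...]
    emptied: tuple[str, ...]


@dataclass
class SelectionResult:
    """Final non-redundant bin set plus the per-iteration audit log.

    ``final`` is ordered by extraction; scores along it need not be
    monotone because rescoring after contig removal can raise a later
    candidate's score.  Final bins are pairwise disjoint in contigs.
    """

    final: list[tuple[CandidateBin, BinScore]] = field(default_factory=list)
    log: list[IterationRecord] = field(default_factory=list)

    @property
    def final_uids(self) -> list[str]:
        return [b.uid for b, _ in self.final]

    def as_bin_map(self) -> dict[str, set[str]]:
        return {b.uid: set(b.contigs) for b, _ in self.final}


def _sort_key(entry: tuple[CandidateBin, BinScore]):
    bin_, bs = entry
    return (-bs.score, -bin_.n50, -bin_.size_bp, bin_.uid)


def select_next(candidates: Iterable[tuple[CandidateBin, BinScore]]) -> str:
    """Uid of the next bin to extract under the full tie-break cascade."""
    pool = list(candidates)
    if not pool:
        raise ValueError("cannot select from an empty candidate pool")
    return min(pool, key=_sort_key)[0].uid


def _tie_break_level(pool: list[tuple[CandidateBin, BinScore]], chosen: tuple[CandidateBin, BinScore]) -> str:
    ties = [e for e in pool if e[1].score == chosen[1].score]
    if len(ties) == 1:
        return "score"
    ties = [e for e in ties if e[0].n50 == chosen[0].n50]
    if len(ties) == 1:
        return "n50"
    ties = [e for e in ties if e[0].size_bp == chosen[0].size_bp]
    return "size_bp" if len(ties) == 1 else "uid"


def dereplicate_select(
    candidates: list[CandidateBin],
    ann: SCGAnnotation,
    refs: Mapping[str, ReferenceSCGSet],
    params: ScoringParams,
    assembly: Mapping[str, int] | None = None,
    release_subthreshold: bool = False,
) -> SelectionResult:
    """Run the full selection loop over a redundant candidate set.

    ``assembly`` maps contig id to length (or is an iterable of Contig);
    it is required because rescoring recomputes bin sizes and N50s.  Input candidates are not mutated; the returned final bins are frozen
    copies taken at extraction time.
    """
    if assembly is None:
        raise ValueError("assembly contig lengths are required for rescoring")
    lengths = as_length_map(assembly)

    pool: dict[str, tuple[CandidateBin, BinScore]] = {}
    for cand in candidates:
        work = cand.copy()
        work.refresh(lengths)
        pool[work.uid] = (work, score_bin(work, ann, refs, params))

    # inverted index: contig -> uids of live candidates containing it
    by_contig: dict[str, set[str]] = {}
    for uid, (work, _) in pool.items():
        for cid in work.contigs:
            by_contig.setdefault(cid, set()).add(uid)

    result = SelectionResult()
    iteration = 0
    while pool:
        iteration += 1
        entries = list(pool.values())
        chosen = min(entries, key=_sort_key)
        bin_, bs = chosen
        if bs.score <= 0:
            break  # continue only while selected bins are above a score of zero
        tie = _tie_break_level(entries, chosen)
        accepted = bs.score > params.t
        del pool[bin_.uid]
        for cid in bin_.contigs:
            by_contig.get(cid, set()).discard(bin_.uid)

        altered: list[str] = []
        emptied: list[str] = []
        claim = accepted or not release_subthreshold
        if claim:
            touched: set[str] = set()
            for cid in bin_.contigs:
                touched |= by_contig.get(cid, set())
            for uid in sorted(touched):
                other, _ = pool[uid]
                removed = other.contigs & bin_.contigs
                other.contigs -= removed
                for cid in removed:
                    by_contig[cid].discard(uid)
                if not other.contigs:
                    del pool[uid]
                    emptied.append(uid)
                else:
                    other.refresh(lengths)
                    pool[uid] = (other, score_bin(other, ann, refs, params))
                    altered.append(uid)

        if accepted:
            result.final.append((bin_.copy(), bs))
        result.log.append(
            IterationRecord(
                iteration=iteration,
                extracted_uid=bin_.uid,
                score=bs.score,
                tie_break=tie,
                accepted=accepted,
                altered=tuple(altered),
                emptied=tuple(emptied),
            )
        )

    _assert_disjoint(result)
    return result


def _assert_disjoint(result: SelectionResult) -> None:
    seen: set[str] = set()
    for bin_, _ in result.final:
        overlap = seen & bin_.contigs
        if overlap:  # pragma: no cover - internal invariant
            raise AssertionError(f"final bins are not disjoint: {sorted(overlap)[:5]}")
        seen |= bin_.contigs
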