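"""Core domain types and basic bin statistics.

The atomic unit of binning is the contig: an assembled sequence fragment
identified by the FASTA record id (token before the first whitespace) and
characterised, for everything this package computes, solely by its length in
base pairs.  A *bin* is a set of contigs hypothesised to derive from one
genome; a *bin set* is the output of one binning tool over one assembly.

Coordinates never matter here: bins are unions of whole contigs, never
contig fragments.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping

__all__ = [
    "Contig",
    "BinSet",
    "CandidateBin",
    "ScoringParams",
    "ReferenceSCGSet",
    "compute_n50",
    "build_candidate_set",
    "as_length_map",
    "default_reference_sets",
    "load_reference_set",
    "DOMAINS",
]

DOMAINS = ("bacteria", "archaea")


@dataclass(frozen=True)
class Contig:
    """An assembled contig: an id and a length in bp (>= 1)."""

    id: str
    length: int

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"contig {self.id!r}: length must be >= 1, got {self.length}")


@dataclass
class BinSet:
    """One binning tool's contig -> bin assignment.

    Within a bin set each contig belongs to at most one bin; this is
    enforced at construction.
    """

    label: str
    bins: dict[str, set[str]]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for bin_id, contigs in self.bins.items():
            for cid in contigs:
                if cid in seen:
                    raise ValueError(
                        f"binner {self.label!r}: contig {cid!r} assigned to both "
                        f"bin {seen[cid]!r} and bin {bin_id!r}"
                    )
                seen[cid] = bin_id

    @property
    def contig_ids(self) -> set[str]:
        out: set[str] = set()
        for contigs in self.bins.values():
            out |= contigs
        return out


@dataclass
class CandidateBin:
    """A candidate genome bin, mutable under contig removal.

    ``uid`` is globally unique across the candidate set (binner label +
    bin id).  ``size_bp`` and ``n50`` are kept consistent with ``contigs``
    via :meth:`refresh`; they feed the selection tie-breaks.
    """

    uid: str
    origin: str
    contigs: set[str]
    size_bp: int = 0
    n50: int = 0

    def refresh(self, lengths: Mapping[str, int]) -> None:
        """Recompute size_bp and n50 from the current contig membership."""
        member_lengths = [lengths[c] for c in self.contigs]
        self.size_bp = sum(member_lengths)
        self.n50 = compute_n50(member_lengths)

    def copy(self) -> "CandidateBin":
        return CandidateBin(self.uid, self.origin, set(self.contigs), self.size_bp, self.n50)


@dataclass(frozen=True)
class ScoringParams:
    """Weights of the bin scoring function.

    b : weight of the duplicate-SCG penalty (dSCG/uSCG term)
    c : weight of the megabin penalty ((sum SCG - uSCG)/rSCG term)
    t : score threshold for admission into the final bin set
    """

    b: float = 0.5
    c: float = 0.5
    t: float = 0.5

    def __post_init__(self) -> None:
        if self.b < 0 or self.c < 0:
            raise ValueError("penalty weights b and c must be non-negative")
        if not 0.0 <= self.t <= 1.0:
            raise ValueError(f"score threshold t must be in [0, 1], got {self.t}")


@dataclass(frozen=True)
class ReferenceSCGSet:
    """The reference single-copy-gene family set of one domain.

    The shipped defaults have 51 bacterial and 38 archaeal families; both
    manifests are plain text files users can replace with their own family
    ids (one per line).
    """

    domain: str
    families: frozenset[str]

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise ValueError(f"unknown domain {self.domain!r}; expected one of {DOMAINS}")
        if not self.families:
            raise ValueError("reference SCG set must be non-empty")

    @property
    def rscg(self) -> int:
        return len(self.families)


def as_length_map(assembly: Iterable[Contig] | Mapping[str, int]) -> dict[str, int]:
    """Normalise an assembly to a contig-id -> length mapping."""
    if isinstance(assembly, Mapping):
        return dict(assembly)
    out: dict[str, int] = {}
    for contig in assembly:
        if contig.id in out:
            raise ValueError(f"duplicate contig id {contig.id!r} in assembly")
        out[contig.id] = contig.length
    return out


def compute_n50(lengths: Iterable[int]) -> int:
    """N50 of a set of contig lengths.

    The minimum length L, itself a member of ``lengths``, such that contigs
    of length >= L sum to at least half the total.  Ties ("exactly 50%")
    count as covered.
    """
    lens = sorted(lengths, reverse=True)
    if not lens:
        raise ValueError("empty bin: N50 is undefined for no contigs")
    if any(l < 1 for l in lens):
        raise ValueError("contig lengths must be >= 1")
    half = 0.5 * sum(lens)
    running = 0
    for l in lens:
        running += l
        if running >= half:
            return l
    raise AssertionError("unreachable")  # pragma: no cover


def build_candidate_set(
    assembly: Iterable[Contig] | Mapping[str, int],
    bin_sets: list[BinSet],
) -> list[CandidateBin]:
    """Aggregate all bins of all binners into one redundant candidate set.

    One CandidateBin per input bin, size and N50 populated.  The same contig
    may appear in candidates from *different* binners (that redundancy is the
    point); within one binner it may not, and every contig must exist in the
    assembly.
    """
    if not bin_sets:
        raise ValueError("need at least one bin set to build a candidate set")
    labels = [bs.label for bs in bin_sets]
    if len(set(labels)) != len(labels):
        raise ValueError(f"binner labels must be unique, got {labels}")
    lengths = as_length_map(assembly)
    candidates: list[CandidateBin] = []
    for bs in bin_sets:
        for bin_id, contigs in bs.bins.items():
            if not contigs:
                raise ValueError(f"binner {bs.label!r}: bin {bin_id!r} is empty")
            unknown = contigs - lengths.keys()
            if unknown:
                raise ValueError(
                    f"binner {bs.label!r}, bin {bin_id!r}: contig(s) not in assembly: "
                    f"{sorted(unknown)[:5]}"
                )
            cand = CandidateBin(uid=f"{bs.label}.{bin_id}", origin=bs.label, contigs=set(contigs))
            cand.refresh(lengths)
            candidates.append(cand)
    return candidates


def fasta_record_id(header: str) -> str:
    """Contig identity: the FASTA header token before the first whitespace."""
    return re.split(r"\s", header.strip(), maxsplit=1)[0]


def load_reference_set(path, domain: str) -> ReferenceSCGSet:
    """Load a reference SCG family manifest (one family id per line, '#' comments)."""
    families = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                families.add(line)
    return ReferenceSCGSet(domain=domain, families=frozenset(families))


def default_reference_sets() -> dict[str, ReferenceSCGSet]:
    """The shipped 51-family bacterial and 38-family archaeal reference sets."""
    out = {}
    for domain, fname in (("bacteria", "bacteria_scg.txt"), ("archaea", "archaea_scg.txt")):
        text = resources.files("consbin.data").joinpath(fname).read_text()
        families = frozenset(
            line.strip() for line in text.splitlines() if line.strip() and not line.startswith("#")
        )
        out[domain] = ReferenceSCGSet(domain=domain, families=families)
    return out
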