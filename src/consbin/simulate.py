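"""Synthetic communities and corrupted binnings for end-to-end testing.

The generator emulates exactly the inputs a consensus-binning run needs:
an assembly (contig ids + lengths), single-copy-gene placements, a ground
truth contig-to-genome partition, and several imperfect binnings of the
kind real tools produce.  Sequences are optional — the algorithm never
reads bases — but a random-nucleotide FASTA emitter is provided for I/O
round-trip tests.

A simulated genome is a bag of contigs whose lengths sum to the genome
length; each of its domain's reference SCG families is placed on exactly
one contig unless dropped at the missing-family rate.  A simulated binner
is the truth partition pushed through a corruption pipeline: megabin
formation, pairwise merges, bin splits, contig misassignment, unbinning —
the characteristic failure modes of composition/coverage binners.

Randomness is seeded; per-binner corruption uses a named substream derived
from the master seed, so adding a binner never perturbs the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .core import BinSet, Contig, default_reference_sets
from .evaluation import ReferenceMap
from .scg import SCGAnnotation

__all__ = [
    "SimConfig",
    "BinnerProfile",
    "Fixture",
    "generate_community",
    "corrupt_binning",
    "generate_benchmark",
    "random_sequences",
]


@dataclass(frozen=True)
class BinnerProfile:
    """Corruption rates of one simulated binner; all rates in [0, 1]."""

    split_rate: float = 0.0
    merge_rate: float = 0.0
    misassign_rate: float = 0.0
    unbinned_rate: float = 0.0
    megabin_prob: float = 0.0

    def __post_init__(self) -> None:
        for name in ("split_rate", "merge_rate", "misassign_rate", "unbinned_rate", "megabin_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a synthetic community.

    Defaults emulate a modest constructed community: 25 genomes of which 3
    are archaeal, genome lengths log-uniform between 0.5 and 5 Mb,
    contigs between 5 and 200 kb, and a 5% chance of any single SCG family
    being lost to incomplete assembly.  ``seed`` is mandatory.
    """

    seed: int
    n_genomes: int = 25
    n_archaea: int = 3
    genome_length_bounds: tuple[int, int] = (500_000, 5_000_000)
    contig_length_bounds: tuple[int, int] = (5_000, 200_000)
    missing_family_rate: float = 0.05
    common_strain_fraction: float = 0.2
    n_circular: int = 0
    circular_length_bounds: tuple[int, int] = (2_000, 50_000)

    def __post_init__(self) -> None:
        if self.n_genomes < 1 or not 0 <= self.n_archaea <= self.n_genomes:
            raise ValueError("need n_genomes >= 1 and 0 <= n_archaea <= n_genomes")
        if not 0.0 <= self.missing_family_rate <= 1.0:
            raise ValueError("missing_family_rate must be in [0, 1]")
        lo, hi = self.contig_length_bounds
        glo, ghi = self.genome_length_bounds
        if lo < 1 or lo > hi or glo < 1 or glo > ghi:
            raise ValueError("length bounds must satisfy 1 <= lo <= hi")
        if lo > glo:
            raise ValueError(
                "infeasible config: minimum contig length exceeds minimum genome length"
            )


@dataclass
class Fixture:
    """Everything a full pipeline run needs, generated in memory."""

    assembly: dict[str, int]  # contig id -> length
    annotation: SCGAnnotation
    truth: BinSet
    binnings: list[BinSet]
    ref_map: ReferenceMap
    genome_quality: dict[str, tuple[float, float]]  # genome -> (completeness %, contamination %)


def _stream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible substream of a master seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(zlib.crc32(name.encode()),)))


def _fragment(total: int, bounds: tuple[int, int], rng: np.random.Generator) -> list[int]:
    """Contig lengths summing exactly to ``total``, each within bounds where possible."""
    lo, hi = bounds
    lengths: list[int] = []
    remaining = total
    while remaining > hi:
        draw = int(rng.integers(lo, hi + 1))
        if remaining - draw < lo:
            draw = remaining  # absorb the short remainder; may slightly exceed hi
        lengths.append(draw)
        remaining -= draw
    if remaining > 0:
        lengths.append(remaining)
    return lengths


def generate_community(cfg: SimConfig) -> Fixture:
    """Generate the assembly, SCG placements, truth partition and reference map.

    Deterministic given the seed.  With missing_family_rate 0 every genome
    carries each of its domain's reference families exactly once, so every
    truth bin scores exactly 1.
    """
    refs = default_reference_sets()
    rng = _stream(cfg.seed, "community")
    assembly: dict[str, int] = {}
    ann = SCGAnnotation()
    truth_bins: dict[str, set[str]] = {}
    contig_map: dict[str, tuple[str, int]] = {}
    genome_lengths: dict[str, int] = {}
    strain_class: dict[str, str] = {}
    circular: dict[str, bool] = {}

    glo, ghi = cfg.genome_length_bounds
    for i in range(cfg.n_genomes):
        domain = "archaea" if i < cfg.n_archaea else "bacteria"
        gid = f"genome_{i:03d}"
        length = int(np.exp(rng.uniform(np.log(glo), np.log(ghi))))
        pieces = _fragment(length, cfg.contig_length_bounds, rng)
        cids = []
        for j, plen in enumerate(pieces):
            cid = f"{gid}_c{j:04d}"
            assembly[cid] = plen
            contig_map[cid] = (gid, plen)
            cids.append(cid)
        truth_bins[gid] = set(cids)
        genome_lengths[gid] = sum(pieces)
        strain_class[gid] = (
            "common_strain" if rng.random() < cfg.common_strain_fraction else "unique_strain"
        )
        circular[gid] = False
        for family in sorted(refs[domain].families):
            if rng.random() < cfg.missing_family_rate:
                continue
            host = cids[int(rng.integers(0, len(cids)))]
            ann.add(host, family, domain, gene_id=f"{gid}.{family}")

    clo, chi = cfg.circular_length_bounds
    for k in range(cfg.n_circular):
        gid = f"circular_{k:03d}"
        cid = f"{gid}_c0000"
        length = int(rng.integers(clo, chi + 1))
        assembly[cid] = length
        contig_map[cid] = (gid, length)
        truth_bins[gid] = {cid}
        genome_lengths[gid] = length
        strain_class[gid] = "unique_strain"
        circular[gid] = True

    ref_map = ReferenceMap(
        contig_to_genome=contig_map,
        genome_lengths=genome_lengths,
        strain_class=strain_class,
        circular=circular,
    )
    quality = {gid: (100.0, 0.0) for gid in genome_lengths}
    return Fixture(
        assembly=assembly,
        annotation=ann,
        truth=BinSet(label="truth", bins=truth_bins),
        binnings=[],
        ref_map=ref_map,
        genome_quality=quality,
    )


def corrupt_binning(
    truth: BinSet,
    profile: BinnerProfile,
    seed: int,
    label: str = "corrupted",
) -> BinSet:
    """Degrade the truth partition into a realistic imperfect binning.

    Corruptions apply in order: megabin formation, pairwise merges, bin
    splits, contig misassignment, unbinning.  The output still assigns
    each contig to at most one bin; with all rates zero it equals the
    truth partition (up to bin renaming).
    """
    rng = _stream(seed, f"corrupt:{label}")
    bins: list[set[str]] = [set(truth.bins[k]) for k in sorted(truth.bins)]

    # megabin: with some probability, collapse several bins into one
    if len(bins) >= 2 and rng.random() < profile.megabin_prob:
        k = int(rng.integers(2, min(5, len(bins)) + 1))
        idx = sorted(rng.choice(len(bins), size=k, replace=False), reverse=True)
        mega: set[str] = set()
        for i in idx:
            mega |= bins.pop(i)
        bins.append(mega)

    # pairwise merges
    order = list(rng.permutation(len(bins)))
    merged: list[set[str]] = []
    i = 0
    while i < len(order):
        if i + 1 < len(order) and rng.random() < profile.merge_rate:
            merged.append(bins[order[i]] | bins[order[i + 1]])
            i += 2
        else:
            merged.append(bins[order[i]])
            i += 1
    bins = merged

    # splits
    split_out: list[set[str]] = []
    for b in bins:
        members = sorted(b)
        if len(members) >= 2 and rng.random() < profile.split_rate:
            cut = int(rng.integers(1, len(members)))
            picked = rng.permutation(len(members))
            left = {members[j] for j in picked[:cut]}
            split_out.extend([left, set(members) - left])
        else:
            split_out.append(set(members))
    bins = split_out

    # contig misassignment across bins
    if len(bins) >= 2 and profile.misassign_rate > 0:
        for i, b in enumerate(bins):
            for cid in sorted(b):
                if rng.random() < profile.misassign_rate:
                    j = int(rng.integers(0, len(bins) - 1))
                    if j >= i:
                        j += 1
                    b.discard(cid)
                    bins[j].add(cid)

    # unbinning
    if profile.unbinned_rate > 0:
        for b in bins:
            for cid in sorted(b):
                if rng.random() < profile.unbinned_rate:
                    b.discard(cid)
    bins = [b for b in bins if b]

    bins.sort(key=lambda b: min(b))
    return BinSet(label=label, bins={f"bin_{i:03d}": b for i, b in enumerate(bins)})


# Realistic default corruption ranges for simulated binners: real tools
# split and merge genomes routinely, misassign a small fraction of contigs,
# leave a chunk of the assembly unbinned, and occasionally emit a megabin.
_PROFILE_RANGES = {
    "split_rate": (0.0, 0.30),
    "merge_rate": (0.0, 0.25),
    "misassign_rate": (0.0, 0.10),
    "unbinned_rate": (0.0, 0.25),
    "megabin_prob": (0.0, 0.30),
}


def generate_benchmark(
    cfg: SimConfig,
    n_binners: int = 5,
    profiles: list[BinnerProfile] | None = None,
) -> Fixture:
    """A community plus ``n_binners`` independently corrupted binnings.

    Each simulated binner gets its own corruption profile — supplied
    explicitly, or drawn uniformly from the default ranges using a named
    substream per binner — and its own corruption seed stream.
    """
    if n_binners < 1:
        raise ValueError("need at least one simulated binner")
    if profiles is not None and len(profiles) != n_binners:
        raise ValueError("one profile per binner required")
    fixture = generate_community(cfg)
    for i in range(n_binners):
        label = f"binner_{i:02d}"
        if profiles is None:
            prng = _stream(cfg.seed, f"profile:{label}")
            profile = BinnerProfile(**{
                name: float(prng.uniform(lo, hi)) for name, (lo, hi) in _PROFILE_RANGES.items()
            })
        else:
            profile = profiles[i]
        fixture.binnings.append(
            corrupt_binning(fixture.truth, profile, seed=cfg.seed, label=label)
        )
    return fixture


def random_sequences(assembly: dict[str, int], seed: int) -> dict[str, str]:
    """Random nucleotide sequences matching the assembly lengths (for I/O tests)."""
    rng = _stream(seed, "sequences")
    bases = np.frombuffer(b"ACGT", dtype="S1")
    return {
        cid: b"".join(rng.choice(bases, size=length)).decode()
        for cid, length in sorted(assembly.items())
    }
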