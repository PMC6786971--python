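"""Independent brute-force oracles for cross-checking the implementation.

Everything here is written from the method's rules directly, sharing no
code with the package: scores are recounted from scratch every iteration,
N50 is the exhaustive max-feasible-threshold definition, and the selection
replay literally re-sorts the whole pool each round.  Slow on purpose.
"""

from __future__ import annotations


def brute_force_n50(lengths: list[int]) -> int:
    """Largest member length L such that contigs >= L cover at least half."""
    total = sum(lengths)
    feasible = [L for L in set(lengths) if sum(x for x in lengths if x >= L) >= 0.5 * total]
    return max(feasible)


def brute_force_score(
    contigs: set[str],
    annotation: dict[str, list[tuple[str, str]]],  # contig -> [(family, domain)]
    ref_families: dict[str, set[str]],  # domain -> families
    b: float,
    c: float,
) -> float:
    """Domain-max SCG score, recounted naively."""
    best = None
    for domain in sorted(ref_families):
        fams = ref_families[domain]
        copies: dict[str, int] = {}
        for cid in contigs:
            for family, dom in annotation.get(cid, []):
                if dom == domain and family in fams:
                    copies[family] = copies.get(family, 0) + 1
        u = len(copies)
        d = sum(1 for v in copies.values() if v >= 2)
        tot = sum(copies.values())
        r = len(fams)
        # parenthesised exactly as the score definition: b·(d/u), c·((Σ−u)/r)
        s = u / r - (b * (d / u) if u else 0.0) - c * ((tot - u) / r)
        if best is None or s > best:
            best = s
    return best


def brute_force_select(
    bins: dict[str, set[str]],  # uid -> contigs
    lengths: dict[str, int],
    annotation: dict[str, list[tuple[str, str]]],
    ref_families: dict[str, set[str]],
    b: float,
    c: float,
    t: float,
) -> list[tuple[str, frozenset]]:
    """Literal replay of the selection rules; returns accepted (uid, contigs)."""
    pool = {uid: set(cs) for uid, cs in bins.items()}
    final: list[tuple[str, frozenset]] = []
    while pool:
        ranked = []
        for uid, cs in pool.items():
            score = brute_force_score(cs, annotation, ref_families, b, c)
            n50 = brute_force_n50([lengths[x] for x in cs])
            size = sum(lengths[x] for x in cs)
            ranked.append((-score, -n50, -size, uid, score, cs))
        ranked.sort()
        _, _, _, uid, score, contigs = ranked[0]
        if score <= 0:
            break
        del pool[uid]
        if score > t:
            final.append((uid, frozenset(contigs)))
        for other_uid in list(pool):
            pool[other_uid] -= contigs
            if not pool[other_uid]:
                del pool[other_uid]
    return final


def brute_force_eval(
    bin_contigs: set[str],
    lengths: dict[str, int],
    contig_to_genome: dict[str, tuple[str, int]],
    genome_lengths: dict[str, int],
) -> tuple[str | None, float, float, float]:
    """Best genome, precision, recall, F1 by exhaustive overlap counting."""
    overlaps: dict[str, int] = {g: 0 for g in genome_lengths}
    for cid in bin_contigs:
        if cid in contig_to_genome:
            g, bp = contig_to_genome[cid]
            overlaps[g] += bp
    bin_size = sum(lengths[c] for c in bin_contigs)
    best = None
    for g in sorted(overlaps):
        if overlaps[g] == 0:
            continue
        if best is None:
            best = g
            continue
        fg, fb = overlaps[g] / bin_size, overlaps[best] / bin_size
        if fg > fb or (fg == fb and genome_lengths[g] > genome_lengths[best]):
            best = g  # equal fraction and length: earlier (smaller) id kept
    if best is None:
        return None, 0.0, 0.0, 0.0
    p = overlaps[best] / bin_size
    r = overlaps[best] / genome_lengths[best]
    f1 = 0.0 if p + r == 0 else 2 * p * r / (p + r)
    return best, p, r, f1


def random_instance(rng):
    """A tiny random selection problem: <= 6 bins, <= 12 contigs, 2 domains."""
    n_contigs = int(rng.integers(3, 13))
    contig_ids = [f"c{i}" for i in range(n_contigs)]
    lengths = {cid: int(rng.integers(1, 101)) for cid in contig_ids}
    families = {"bacteria": {"bf1", "bf2", "bf3"}, "archaea": {"af1", "af2"}}
    annotation: dict[str, list[tuple[str, str]]] = {}
    for cid in contig_ids:
        n_genes = int(rng.integers(0, 3))
        for g in range(n_genes):
            domain = "bacteria" if rng.random() < 0.7 else "archaea"
            family = sorted(families[domain])[int(rng.integers(0, len(families[domain])))]
            annotation.setdefault(cid, []).append((family, domain))
    n_binners = int(rng.integers(1, 4))
    bins: dict[str, set[str]] = {}
    origins: dict[str, str] = {}
    k = 0
    for bi in range(n_binners):
        remaining = [cid for cid in contig_ids if rng.random() < 0.8]
        rng.shuffle(remaining)
        while remaining and k < 6:
            take = int(rng.integers(1, min(len(remaining), 5) + 1))
            uid = f"binner{bi}.b{k}"
            bins[uid] = set(remaining[:take])
            origins[uid] = f"binner{bi}"
            remaining = remaining[take:]
            k += 1
    if not bins:
        bins["binner0.b0"] = {contig_ids[0]}
        origins["binner0.b0"] = "binner0"
    b = float(rng.choice([0.0, 0.3, 0.5, 1.0]))
    c = float(rng.choice([0.0, 0.3, 0.5, 1.0]))
    t = float(rng.choice([0.0, 0.3, 0.5]))
    return lengths, annotation, bins, origins, b, c, t
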