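"""Score genome bins from single-copy-gene tallies.

The bin score is uSCG/rSCG − b·dSCG/uSCG − c·(ΣSCG − uSCG)/rSCG: the
fraction of reference single-copy families present, minus penalties for
duplicated families and for total surplus copies.  A complete clean bin
scores 1; a merged two-genome "megabin" scores about 0.
"""

from consbin import ScoringParams, default_reference_sets, score_counts
from consbin.scg import SCGCounts

refs = default_reference_sets()
params = ScoringParams(b=0.5, c=0.5, t=0.5)

cases = [
    ("complete clean bacterial bin", SCGCounts("bacteria", 51, 0, 51)),
    ("partial bin, some duplicates", SCGCounts("bacteria", 40, 5, 45)),
    ("two complete genomes merged", SCGCounts("bacteria", 51, 51, 102)),
    ("complete clean archaeal bin", SCGCounts("archaea", 38, 0, 38)),
    ("no single-copy genes at all", SCGCounts("bacteria", 0, 0, 0)),
]
for label, counts in cases:
    s = score_counts(counts, refs[counts.domain], params)
    print(f"{label:32s} uSCG={counts.uscg:3d} dSCG={counts.dscg:3d} "
          f"SSCG={counts.total:3d}  score={s:+.6f}")

print("\nScores near 1 mean complete and uncontaminated; near or below 0, "
      "either empty or a multi-genome megabin.")
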