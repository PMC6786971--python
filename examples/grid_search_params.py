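"""Grid search over the scoring weights b, c and the threshold t.

On a synthetic 25-genome community (22 bacteria + 3 archaea) binned by
five corrupted binners, run the selection at every parameter combination
and report bin counts and accuracy.  Raising t trades bin count for
precision; the objective column adds the quality-bin fraction, mean
precision and mean recall.
"""

from consbin import (
    SimConfig, build_candidate_set, default_reference_sets, generate_benchmark,
    grid_search,
)

fx = generate_benchmark(SimConfig(seed=77, n_genomes=25, n_archaea=3), n_binners=5)
candidates = build_candidate_set(fx.assembly, fx.binnings)

table = grid_search(candidates, fx.annotation, default_reference_sets(), fx.assembly,
                    b_values=[0, 0.5, 1], c_values=[0, 0.5, 1],
                    t_values=[0.1, 0.3, 0.5, 0.7, 0.9], eval_ref=fx.ref_map)

print(table[(table.b == 0.5) & (table.c == 0.5)].to_string(index=False))
print("\nOptimal combinations (max quality-fraction + precision + recall):")
print(table[table.is_optimum][["b", "c", "t", "n_quality_bins",
                               "mean_precision", "mean_recall"]].to_string(index=False))
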