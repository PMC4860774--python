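"""Merge duplicate runs by rank summation and size the candidate list.

Duplicate screens are merged by ranking each run's gene scores (most
suppressive first) and summing the ranks.  The number of genes to carry
into network analysis is chosen by scanning list sizes from 50 in steps
of 25 and keeping the size whose top genes correlate best between the two
runs.  A composite score (product of two screens' scores) flags genes
suppressive in both this screen and an orthogonal recombination-activity
screen.
"""

from radscreen import (
    call_hits,
    hrr_composite_score,
    rank_and_merge,
    simulate_score_pairs,
    size_candidate_list,
)

s1, s2, true_hits = simulate_score_pairs(
    n_genes=10_000, hit_fraction=0.02, hit_shift=-3.0, seed=7
)
merged = rank_and_merge(s1, s2)
print(f"merged {len(merged.table)} genes scored in both runs")

sizing = size_candidate_list(merged, start=50, step=25, max_size=600)
print(f"candidate-list sizing: chose {sizing.chosen_size} genes "
      f"(correlation {sizing.correlations[list(sizing.sizes).index(sizing.chosen_size)]:.3f})")

top = set(merged.table.index[: sizing.chosen_size])
recovered = len(top & true_hits) / len(true_hits)
print(f"the chosen list captures {recovered:.0%} of the {len(true_hits)} "
      "planted hits")

hits1 = call_hits(s1, -2.0)
hits2 = call_hits(s2, -2.0)
print(f"genes below -2: {len(hits1)} (run 1), {len(hits2)} (run 2), "
      f"{len(hits1 & hits2)} in both")

# composite score against a second, independent screen of the same genes
ext, _, _ = simulate_score_pairs(n_genes=10_000, hit_fraction=0.02,
                                 hit_shift=-3.0, seed=8)
comp = hrr_composite_score(merged.table["mean_score"], ext)
both_neg = comp["suppressor_rank"].notna().sum()
print(f"composite scores for {len(comp)} shared genes; "
      f"{both_neg} negative in both screens (candidate suppressors of both "
      "readouts)")
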