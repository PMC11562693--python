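"""Dual-layout robustness and duplicate/identity analysis.

Runs the full fingerprinting pipeline on a synthetic panel with injected
duplicate accessions and mislabel swaps: calls dosages under the pooled
("original") and per-source-plate ("single") layouts, compares and
combines them, filters markers by layout disagreement, and checks
molecular identity over the robust accession subset.
"""

import numpy as np

from polyfp import (
    ScoreMatrix,
    call_layout,
    classify_pair,
    combine_layout_calls,
    compare_layout_calls,
    find_identical_clusters,
    generate_truth_panel,
    inject_duplicates_and_mislabels,
    marker_robustness_filter,
    min_markers_required,
    robust_subset,
    simulate_fluorescence,
)

truth = generate_truth_panel(n_accessions=300, n_markers=18, seed=7)
truth = inject_duplicates_and_mislabels(truth, n_duplicates=6, n_mislabels=1)
records = simulate_fluorescence(truth)

single, _ = call_layout(records, layout="single")
original, _ = call_layout(records, layout="original")
combined, conflicts = combine_layout_calls(single, original)
print(f"call rates: single {single.call_rate():.3f}, "
      f"original {original.call_rate():.3f}, "
      f"combined {combined.call_rate():.3f} "
      f"({len(conflicts)} conflicting cells)")

comps = compare_layout_calls(single, original)
retained, excluded = marker_robustness_filter(comps)
print(f"markers retained after the 10% layout-disagreement filter: "
      f"{len(retained)}/{len(comps)}")

# identity analysis on accessions called completely and identically in
# both layouts
robust = robust_subset(single, original, retained)
print(f"robust accessions (complete + layout-identical): {len(robust)}")
clusters, unique = find_identical_clusters(
    ScoreMatrix(combined.scores.loc[robust, retained])
)
print(f"identical-profile clusters: {len(clusters)} "
      f"({sum(len(c.members) for c in clusters)} accessions); "
      f"{len(unique)} unique profiles")

verdicts = [
    classify_pair(combined.scores.loc[a], combined.scores.loc[b]).category
    for a, b in truth.duplicate_pairs
]
print("injected duplicate pairs classified as:", verdicts)
print(f"markers needed to distinguish {len(robust)} genotypes in theory: "
      f"{min_markers_required(max(len(robust), 1))}")
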