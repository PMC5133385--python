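"""Replicate concordance: correlations and clustering of the 16 datasets.

After normalization, each dataset is a gene vector of normalized colony
sizes.  Technical repeats (same template plates) should agree closely;
biological repeats (independent platings) agree less — the dendrogram
should pair every t1/t2 duo as sibling leaves.
"""

import respscreen as rs
from respscreen.phenotype import screen_long_table
from respscreen.pipeline import NormalizationConfig, normalize_screen
from respscreen.qc_stats import (
    cluster_datasets,
    correlation_matrix,
    dataset_matrix,
    replicate_concordance,
)

params = rs.SimulationParams(n_genes=192, grid_rows=8, grid_cols=12, seed=1)
layout, annotation, grids, truth = rs.simulate_default_screen(seed=1, params=params)
norm = normalize_screen(grids, layout, NormalizationConfig())

matrix = dataset_matrix(screen_long_table(norm, layout))
corr = correlation_matrix(matrix)
concord = replicate_concordance(corr)
print(f"mean Pearson r within technical-repeat pairs:  "
      f"{concord['mean_r_within_technical']:.3f} ({concord['n_technical_pairs']} pairs)")
print(f"mean Pearson r between biological repeats:     "
      f"{concord['mean_r_between_biological']:.3f} ({concord['n_biological_pairs']} pairs)")
print("technical repeats agree more closely than biological repeats, so "
      "ratios are computed per biological repeat, never averaged across them")

clusters = cluster_datasets(matrix)  # Euclidean + Ward on unsquared distances
cherries = sorted(tuple(sorted(c)) for c in clusters.leaf_cherries())
print(f"\ndendrogram cherries ({len(cherries)} sibling-leaf pairs):")
for a, b in cherries:
    print(f"  {a}  <->  {b}")
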