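"""Generate a synthetic colony-array screen and look at its structure.

Builds a small deletion-library screen (192 strains on two 8x12 plates,
16 datasets) with plate-scale, edge and spatial artefacts plus planted
respiratory-deficient strains, and prints what the generator put in.
"""

import numpy as np

import respscreen as rs

params = rs.SimulationParams(n_genes=192, grid_rows=8, grid_cols=12, seed=1)
layout, annotation, grids, truth = rs.simulate_default_screen(seed=1, params=params)

print(f"{layout.n_genes} strains arrayed on {layout.n_plates} plates "
      f"({layout.grid_rows}x{layout.grid_cols}); "
      f"{layout.n_empty_positions()} empty positions")
print(f"{len(grids)} plate grids = 2 backgrounds x 2 media x 2 bio x 2 tech "
      f"x {layout.n_plates} plates")
print(f"annotated ('mitochondrion'): {len(annotation.annotated)} genes "
      f"({100 * annotation.prevalence:.1f}% of the library)")
defi = truth.deficient_genes
print(f"respiratory-deficient strains: {len(defi)}, of which "
      f"{len(defi & annotation.annotated)} are annotated "
      f"(deficiency is concentrated in the annotated set)")

grid = next(iter(grids.values()))
border = np.zeros(grid.shape, dtype=bool)
border[[0, -1], :] = border[:, [0, -1]] = True
print(f"first plate ({grid.key.label}): border mean "
      f"{grid.sizes[border & ~grid.missing].mean():.0f} px vs interior "
      f"{grid.sizes[~border & ~grid.missing].mean():.0f} px "
      f"- the edge effect the normalization must remove")
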