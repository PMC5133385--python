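"""Compare hit lists across screens as a Venn partition over a shared universe.

Screens of the same phenotype in different libraries or labs overlap only
partially; the comparison is made over a declared universe (e.g. genes
present in the deletion library and ortholog-mapped in both species).
"""

import numpy as np

from respscreen.hitcalling import compare_gene_sets, merge_backgrounds

rng = np.random.default_rng(1)
universe = [f"SPS{i:04d}" for i in range(1, 501)]

# two in-house hit lists (one per genetic background) and an external screen
aux = set(rng.choice(universe, 60, replace=False))
proto = set(rng.choice(universe, 45, replace=False)) | set(list(aux)[:20])
previous = set(rng.choice(universe, 80, replace=False)) | set(list(aux)[:15])

merged = merge_backgrounds(aux, proto)
print(f"merged in-house hits (union of backgrounds): {len(merged)} genes")

cmp = compare_gene_sets({"new_screen": merged, "previous_screen": previous},
                        universe)
print(f"only new screen:      {cmp.count('new_screen')}")
print(f"shared:               {cmp.count('new_screen', 'previous_screen')}")
print(f"only previous screen: {cmp.count('previous_screen')}")
print(f"union:                {cmp.union_size} genes "
      "(partial overlap is expected: respiratory phenotypes vary strongly "
      "between libraries and repeats)")
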