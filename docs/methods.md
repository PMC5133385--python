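# Methods

## The analysis problem

A colony-array screen measures strain fitness as colony area on agar
plates. Identifying respiratory-deficient deletion mutants requires
comparing each strain's growth on a non-fermentable carbon source
(glycerol, which forces respiration) with its growth on glucose (control,
fermentation). The raw signal is confounded by technical structure:
plate-to-plate scale differences, systematic growth advantages in border
rows/columns, smooth local variation of the agar surface, failed pinnings,
and substantial run-to-run variability — independent replatings
("biological repeats") agree far less than replicate pinnings from the same
template ("technical repeats"). The pipeline normalizes within plates,
averages only technical repeats, filters unreliable measurements, forms the
glycerol/glucose ratio per biological repeat, and calls hits where both
biological repeats agree, using a functional annotation (GO
'mitochondrion') to choose the ratio cutoff.

## Normalization model

All corrections are multiplicative: colony areas are positive, and plate
scans differ by scale factors, so the observed size is modelled as
signal × plate scale × row factor × column factor × smooth local field ×
noise. The steps, each exposed separately and composed by
`normalize_plate`:

1. **Absent-colony masking.** Size 0 encodes a non-grown or empty position;
   masked positions are excluded from every subsequent statistic.
2. **Plate-median division.** Makes plates comparable; the non-missing
   median is exactly 1 afterwards, an invariant maintained by every later
   stage (stages 3–4 end with an explicit rescale).
3. **Row/column correction.** Each row is divided by its non-missing
   median, then each column of the result by its median. A separable
   row × column artefact is removed exactly in one pass on a complete grid;
   an optional `polish_iterations > 1` repeats the alternating pass for
   non-separable residuals. Rows/columns with fewer than `min_count`
   (default 3) non-missing entries are left uncorrected — an unstable
   median is worse than no correction.
4. **Local median filter.** Each colony is divided by the median of its
   `window × window` (default 3×3) neighborhood, truncated at borders,
   non-missing entries only, center included. A smooth artefact field is
   its own neighborhood median and is removed; a single deviating colony is
   its neighborhood's outlier, not its median, and survives unchanged. The
   guarantee is for *isolated* deviations: if deviating colonies occupy
   half or more of a (truncated, e.g. corner) neighborhood they shift the
   local median and distort nearby values — unavoidable for any local
   robust filter, and the reason the filter uses the smallest window that
   defines "local".

Medians of even-length samples are the midpoint of the two central order
statistics. Every step is scale-free: `normalize_plate(α·G) =
normalize_plate(G)` for any α > 0, which also makes the downstream ratio
phenotype invariant to plate-level scale in either condition.

The step order (plate median → row/column → median filter) is fixed; the
three corrections are listed in that order in descriptions of such screens
and composing them sequentially is the simplest consistent reading. Row
before column (rather than simultaneous fitting) is likewise the simplest
interpretation; the polish option covers cases where order matters.

## Phenotype and quality filters

Technical repeats are averaged per (gene, background, medium, biological
repeat); the standard error is the sample SD over √n (with two repeats,
|x₁−x₂|/2; zero for a single value). Three filters are applied per entry,
with strict inequalities (SE exactly 0.4 and glucose mean exactly 0.12
pass):

- SE > 0.4 between technical repeats (unreliable measurement);
- colony absent in at least one technical repeat;
- mean normalized glucose size < 0.12 — a strain that barely grows on the
  control medium would produce an explosive, meaningless ratio.

The SE filter is applied on both media (whether it should apply only to
glucose is ambiguous; per-condition application is the conservative
choice). All filters act per biological repeat, because ratios are formed
per biological repeat — the between-repeat variability of such screens is
too large to justify averaging, so each biological repeat yields its own
hit ranking and the final list requires agreement between repeats.

## Replicate statistics

Dataset vectors are normalized sizes (not ratios): the 16 datasets are
media-specific, and concordance is assessed before any ratio is formed.
Correlations are Pearson on pairwise-complete genes (pairs with fewer than
3 shared genes are reported missing). Clustering uses Euclidean distances
over complete-case genes and Ward agglomeration in the convention that
applies the Lance–Williams Ward update to the *unsquared* distances
(R's `hclust(method="ward.D")`). Implementation note: scipy's Ward on a
condensed distance matrix applies the update to squared distances and
reports square roots, so feeding it √d and squaring the reported heights
reproduces the plain-Ward recurrence exactly; the test suite verifies this
against a brute-force agglomeration. The squared-distance convention
("ward.D2") is available as an option. Leaf identity is made deterministic
by sorting column labels before clustering.

## Enrichment and threshold selection

Enrichment of a hit list is the one-sided hypergeometric upper tail
P(X ≥ k) with the deletion-library genes as the background universe — a
list gene outside the background raises an error rather than silently
shifting the universe. Multiple lists are corrected with
Benjamini–Hochberg (Bonferroni available); the correction method is a
pinned choice, as over-representation services differ here. Annotated
genes absent from the background are retained in the annotation but
excluded from all computations.

The ratio cutoff is selected from the data: over an ascending grid
(default 0.05–1.20, step 0.01, matching two-decimal thresholds), hit lists
L₁(t), L₂(t) = {g : ratio(g) < t} (strict) are formed per biological
repeat, and the percent-annotated of L₁, L₂ and their overlap is tracked.
The selected threshold is the **largest** t at which the overlap keeps
≥ 40% annotated genes — the most lenient cutoff (largest list) that still
meets the enrichment floor, i.e. where the falling enrichment curve
crosses 40% from above. A `min_overlap` guard (default 10 genes) prevents
tiny, unstable lists from qualifying; it is configurable and set to the
smallest list size at which a percentage is meaningfully stable.
Backgrounds are merged by union; cross-screen comparisons are full Venn
partitions over a declared universe (e.g. library ∩ ortholog-mapped
genes), with out-of-universe genes dropped and counted.

## Synthetic screen generator

The generator emulates the screen design: 3420 strains arrayed at 384
colonies (16×24) on 9 plates, in 2 genetic backgrounds × 2 media × 2
biological × 2 technical repeats (16 datasets). Colony sizes compose
multiplicatively:

    size = base · P(plate) · E(row, col) · B(plate, row, col)
                · S(gene) · J(gene, bio) · M(gene, medium, bio) · ε

- `P`: per-physical-plate lognormal scale, CV `plate_effect_cv` (0.15);
- `E`: deterministic edge profile, separable as row × column border
  factors `1 + edge_effect_strength` (0.3) on the outermost ring
  (`edge_depth` 1). Separability matches the row/column-specific artefact
  the normalization removes; corners carry both factors;
- `B`: 1 + sum of Gaussian bumps (per plate: `spatial_blob_count` 2,
  amplitude up to 0.3, σ 3 positions) — the smooth local artefact;
- `S`: per-gene baseline fitness, lognormal CV `strain_effect_cv` (0.15),
  shared by all 16 datasets — strains differ in growth irrespective of
  medium;
- `J`: per-(gene, background, biological repeat) lognormal jitter, CV
  `bio_noise_cv` (0.18) — the between-biological-repeat variation of
  strain effects;
- `M`: 1 on glucose; on glycerol, deficient strains carry a multiplier
  drawn uniformly from `deficiency_effect_range` (0.3–0.8), jittered per
  biological repeat (capped at 1). Non-deficient strains have multiplier
  exactly 1 before noise;
- `ε`: per-colony lognormal technical noise, CV `tech_noise_cv` (0.08, by
  construction ≤ `bio_noise_cv`).

Each position is independently missing (size 0, mask set) with
`missing_prob` (0.02). Deficiency is assigned with probability 0.35 given
the 13%-prevalence 'mitochondrion' annotation and 0.02 otherwise, so
deficient strains are ~70% annotated and recovered hit lists are strongly
enriched. `S` and `J` cancel exactly in the glycerol/glucose ratio, so a
strain's expected ratio phenotype is its (jittered) deficiency multiplier;
their purpose is to give the 16 datasets the correlation structure of real
screens (technical repeats most similar, biological repeats weaker, all
positive), which pure medium-specific effects could not produce on the
glucose side. Noise magnitudes are calibration choices — real screens of
this type do not come with published noise decompositions — picked to
yield technical-pair correlations near 0.85 and biological-pair
correlations near 0.4.

All randomness derives from one integer seed through named substreams
(layout, annotation, deficiency, multipliers, per-dataset-per-plate
effects), making any component independently reproducible and the whole
screen bit-identical across runs.

### What the generator does not emulate

Pixel-level images and segmentation error; competition between neighboring
colonies; agar-thickness or lid-condensation gradients (only their smooth
multiplicative footprint); wild-type contamination and mating/selection
artefacts; genetic interactions of auxotrophy (backgrounds differ only
through independent noise realizations, not systematically). Tests passing
on synthetic screens therefore validate the statistical machinery and its
contracts, not the biology of any particular real dataset.

## Problem sizes and determinism

The test suite runs most checks on 192-gene, two-plate screens and the
end-to-end recovery checks on the full default screen (3420 genes, 144
plate grids), which completes in seconds. Regression values for recovery
(sensitivity/precision of the selected overlap list at seed 1) were pinned
from a first audited run and are asserted exactly; they characterize the
default generator conditions, not a claim about real screens.
`scripts/acceptance.py` recomputes everything from scratch for any seed.

## Known limitations

- The row/column correction assumes separable artefacts; strongly
  non-separable position effects are only attenuated (polish iterations
  help but do not guarantee removal).
- The median filter distorts clustered low-growth colonies in truncated
  border neighborhoods (see above); real screens randomize strain layout,
  which makes large deficient clusters unlikely.
- Threshold selection on a fixed grid reports grid values only; a
  sorted-unique-ratio grid can be supplied where exact cross-over points
  matter.
- With two technical repeats, the SE estimate (|x₁−x₂|/2) has a single
  degree of freedom; the 0.4 cutoff is a blunt but standard guard.
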