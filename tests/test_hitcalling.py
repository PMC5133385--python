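import itertools

import numpy as np
import pandas as pd
import pytest

import respscreen as rs
from respscreen.errors import ConsistencyError, InvalidParameterError
from respscreen.hitcalling import (
    compare_gene_sets,
    merge_backgrounds,
    overlap_hits,
    select_threshold,
    threshold_curve,
)
from respscreen.types import GeneSetAnnotation

from conftest import noise_free_params


def make_ratio_pair(n=60, n_low=12, low=0.5, seed=0):
    """Two repeats: n_low genes at `low` in both, the rest at 1.0."""
    genes = [f"g{i:03d}" for i in range(n)]
    vals = np.where(np.arange(n) < n_low, low, 1.0)
    r1 = pd.Series(vals, index=genes)
    r2 = pd.Series(vals, index=genes)
    ann = GeneSetAnnotation("term", genes[:n_low], genes)  # low genes annotated
    return genes, r1, r2, ann


def test_curve_saturates_at_both_ends():
    genes, r1, r2, ann = make_ratio_pair()
    curve = threshold_curve(r1, r2, ann, grid=np.array([0.1, 0.7, 1.5]))
    t = curve.table.set_index("threshold")
    assert t.loc[0.1, "size_rep1"] == 0 and np.isnan(t.loc[0.1, "pct_rep1"])
    assert t.loc[1.5, "size_rep1"] == len(genes)
    assert t.loc[1.5, "pct_overlap"] == pytest.approx(100.0 * 12 / 60)
    assert curve.background_rate == pytest.approx(20.0)


def test_curve_sizes_monotone_and_overlap_bounded():
    rng = np.random.default_rng(1)
    genes = [f"g{i}" for i in range(100)]
    r1 = pd.Series(rng.uniform(0.2, 1.2, 100), index=genes)
    r2 = pd.Series(rng.uniform(0.2, 1.2, 100), index=genes)
    r1.iloc[::7] = np.nan
    ann = GeneSetAnnotation("term", genes[:13], genes)
    curve = threshold_curve(r1, r2, ann)
    t = curve.table
    for col in ("size_rep1", "size_rep2", "size_overlap"):
        assert np.all(np.diff(t[col]) >= 0)
    assert np.all(t["size_overlap"] <= np.minimum(t["size_rep1"], t["size_rep2"]))


def test_curve_missing_ratios_excluded():
    genes = ["a", "b", "c"]
    r1 = pd.Series([0.3, np.nan, 0.3], index=genes)
    r2 = pd.Series([0.3, 0.3, 0.3], index=genes)
    ann = GeneSetAnnotation("term", ["a"], genes)
    curve = threshold_curve(r1, r2, ann, grid=np.array([1.0]))
    row = curve.table.iloc[0]
    assert row["size_rep1"] == 2
    assert row["size_rep2"] == 3
    assert row["size_overlap"] == 2  # b missing in rep1, excluded from overlap


def test_curve_steps_at_deficiency_multiplier():
    genes, r1, r2, ann = make_ratio_pair(low=0.5)
    curve = threshold_curve(r1, r2, ann, grid=np.array([0.49, 0.5, 0.51]))
    t = curve.table.set_index("threshold")
    assert t.loc[0.49, "size_overlap"] == 0
    assert t.loc[0.50, "size_overlap"] == 0  # strict inequality at the cutoff
    assert t.loc[0.51, "size_overlap"] == 12


def test_curve_rejects_bad_grid_and_disjoint_universes():
    genes, r1, r2, ann = make_ratio_pair()
    with pytest.raises(InvalidParameterError):
        threshold_curve(r1, r2, ann, grid=np.array([0.5, 0.5]))
    other = pd.Series([0.5], index=["zzz"])
    with pytest.raises(ConsistencyError):
        threshold_curve(r1, other, ann)


def test_select_threshold_takes_largest_qualifying():
    genes, r1, r2, ann = make_ratio_pair()
    grid = np.array([0.6, 0.8, 1.01])
    curve = threshold_curve(r1, r2, ann, grid=grid)
    # overlap is the 12 annotated genes (100%) until all 60 enter (20%) at 1.01
    assert select_threshold(curve, min_enrichment=40.0, min_overlap=5) == 0.8
    assert curve.selected == 0.8


def test_select_threshold_saturation_and_none():
    genes, r1, r2, ann = make_ratio_pair()
    curve = threshold_curve(r1, r2, ann, grid=np.array([0.6, 0.8]))
    assert select_threshold(curve, min_enrichment=40.0, min_overlap=5) == 0.8
    assert select_threshold(curve, min_enrichment=100.0, min_overlap=50) is None


def test_select_threshold_min_overlap_guard():
    genes, r1, r2, ann = make_ratio_pair(n_low=3)
    curve = threshold_curve(r1, r2, ann, grid=np.array([0.6]))
    # 3 genes, 100% annotated, but below the minimum overlap size
    assert select_threshold(curve, min_enrichment=40.0, min_overlap=10) is None
    assert select_threshold(curve, min_enrichment=40.0, min_overlap=3) == 0.6


def test_select_threshold_monotone_in_floor():
    rng = np.random.default_rng(3)
    genes = [f"g{i}" for i in range(300)]
    vals1 = rng.uniform(0.2, 1.2, 300)
    vals2 = np.clip(vals1 + rng.normal(0, 0.05, 300), 0.05, None)
    r1 = pd.Series(vals1, index=genes)
    r2 = pd.Series(vals2, index=genes)
    ann = GeneSetAnnotation("term", [g for g, v in zip(genes, vals1) if v < 0.6], genes)
    curve = threshold_curve(r1, r2, ann)
    previous = None
    for floor in (80.0, 60.0, 40.0, 20.0):
        thr = select_threshold(curve, min_enrichment=floor, min_overlap=5)
        if previous is not None and thr is not None and previous is not False:
            assert thr >= previous
        previous = thr if thr is not None else previous


def test_overlap_hits_examples():
    r1 = pd.Series({"a": 0.3, "b": 0.4, "c": 0.9})
    r2 = pd.Series({"a": 0.95, "b": 0.2, "c": 0.2})
    assert overlap_hits(r1, r2, 0.5) == ["b"]
    assert overlap_hits(r1, r1, 0.5) == ["a", "b"]


def test_overlap_hits_strict_inequality():
    r1 = pd.Series({"a": 0.86, "b": 0.85})
    assert overlap_hits(r1, r1, 0.86) == ["b"]


def test_noise_free_screen_overlap_recovers_deficient_set():
    params = noise_free_params(
        frac_deficient_given_annotated=1.0,
        deficiency_effect_range=(0.3, 0.8),
    )
    layout = rs.generate_layout(192, 8, 12, seed=11)
    ann = rs.generate_annotation(layout, 0.15, seed=11)
    grids, truth = rs.simulate_screen(layout, ann, params)
    from respscreen.phenotype import (
        apply_qc_filters,
        compute_ratios,
        ratios_for,
        screen_long_table,
        summarize_technical_table,
    )

    summary = apply_qc_filters(
        summarize_technical_table(screen_long_table(grids, layout)),
        min_glucose=0.12 * params.base_size,
    )
    ratios = compute_ratios(summary)
    r1 = ratios_for(ratios, "auxotroph", 1)
    r2 = ratios_for(ratios, "auxotroph", 2)
    hits = overlap_hits(r1, r2, 0.86)
    want = {g for g in truth.deficient_genes
            if truth.multiplier(1)[g] < 0.86 and truth.multiplier(2)[g] < 0.86}
    assert set(hits) == want


def test_merge_backgrounds_is_union():
    assert merge_backgrounds(["a", "b"], ["b", "c"]) == ["a", "b", "c"]


# ------------------------------------------------------------- comparisons


def test_venn_two_sets():
    cmp = compare_gene_sets({"A": {"a", "b"}, "B": {"b", "c"}},
                            universe={"a", "b", "c", "d"})
    assert cmp.count("A") == 1
    assert cmp.count("B") == 1
    assert cmp.count("A", "B") == 1
    assert cmp.union_size == 3
    assert sum(cmp.region_counts.values()) == cmp.union_size


def test_venn_disjoint_sets():
    cmp = compare_gene_sets({"A": {"a"}, "B": {"b"}}, universe={"a", "b"})
    assert cmp.count("A", "B") == 0


def test_venn_three_sets_matches_bruteforce_enumeration():
    rng = np.random.default_rng(7)
    universe = [f"g{i}" for i in range(40)]
    sets = {name: set(rng.choice(universe, size=12, replace=False))
            for name in "ABC"}
    cmp = compare_gene_sets(sets, universe)
    names = list(sets)
    for included in itertools.chain.from_iterable(
        itertools.combinations(names, r) for r in (1, 2, 3)
    ):
        inc = set(included)
        brute = sum(
            1 for g in universe
            if {n for n in names if g in sets[n]} == inc
        )
        assert cmp.count(*included) == brute
    assert sum(cmp.region_counts.values()) == cmp.union_size


def test_venn_drops_genes_outside_universe():
    cmp = compare_gene_sets({"A": {"a", "x"}, "B": {"b"}}, universe={"a", "b"})
    assert cmp.n_dropped == 1
    assert cmp.union_size == 2


def test_venn_validation():
    with pytest.raises(InvalidParameterError):
        compare_gene_sets({"A": {"a"}, "B": {"b"}}, universe=set())
    with pytest.raises(InvalidParameterError):
        compare_gene_sets({"A": {"a"}}, universe={"a"})
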