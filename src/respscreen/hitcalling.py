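"""Hit calling: enrichment-vs-threshold curves, threshold selection,
replicate-overlap hit lists and cross-screen set comparisons.

Rather than fixing an arbitrary ratio cutoff, the threshold is chosen from
the data: for an ascending grid of candidate cutoffs ``t`` the genes with
ratio < t are listed for each biological repeat, and the percentage of
annotated (e.g. GO 'mitochondrion') genes is tracked for each repeat's list
and for their overlap.  The selected threshold is the *largest* (most
lenient, hence largest hit list) cutoff at which the overlap list still
shows at least ``min_enrichment`` percent annotated genes — the point where
the enrichment curve crosses the floor from above.  A minimum overlap size
guards against unstable percentages on tiny lists.

Hit lists from the two genetic backgrounds are merged by union, and
compared against external gene lists (previous screens, ortholog-based
lists) as full Venn partitions over a declared gene universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConsistencyError, InvalidParameterError
from .types import GeneSetAnnotation

logger = logging.getLogger(__name__)

#: Default ascending grid of candidate ratio cutoffs (0.05 .. 1.20 step 0.01).
DEFAULT_GRID = np.round(np.arange(0.05, 1.20 + 1e-9, 0.01), 10)


@dataclass
class ThresholdCurve:
    """Hit-list sizes and percent-annotated along a threshold grid.

    ``table`` columns: threshold, size_rep1, size_rep2, size_overlap,
    pct_rep1, pct_rep2, pct_overlap (NaN for empty lists);
    ``background_rate`` is the annotation prevalence in percent.
    """

    table: pd.DataFrame
    background_rate: float
    selected: float | None = None


def _counts_along_grid(values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """#{v : v < t} for each grid threshold t (strict inequality)."""
    return np.searchsorted(np.sort(values), grid, side="left")


def threshold_curve(
    ratios_rep1: pd.Series,
    ratios_rep2: pd.Series,
    annotation: GeneSetAnnotation,
    grid: np.ndarray | None = None,
) -> ThresholdCurve:
    """Sweep hit-list sizes and annotation percentages over ratio cutoffs.

    ``ratios_rep1``/``ratios_rep2`` are gene-indexed ratio series of the two
    biological repeats (NaN = filtered).  Genes with a missing ratio in a
    repeat are excluded from that repeat's lists and hence from the overlap.
    """
    if grid is None:
        grid = DEFAULT_GRID
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or (np.diff(grid) <= 0).any():
        raise InvalidParameterError("grid must be a strictly ascending sequence")
    common = set(ratios_rep1.index) & set(ratios_rep2.index)
    if not common:
        raise ConsistencyError("biological repeats share no genes")
    annotation.require_universe(
        set(ratios_rep1.index) | set(ratios_rep2.index)
    )
    ann = annotation.annotated

    r1 = ratios_rep1.dropna()
    r2 = ratios_rep2.dropna()
    both = r1.index.intersection(r2.index)
    overlap_val = np.maximum(
        r1.loc[both].to_numpy(), r2.loc[both].to_numpy()
    )  # gene in both lists iff max(r1, r2) < t
    ann1 = np.fromiter((g in ann for g in r1.index), bool, len(r1))
    ann2 = np.fromiter((g in ann for g in r2.index), bool, len(r2))
    annb = np.fromiter((g in ann for g in both), bool, len(both))

    cols: dict[str, np.ndarray] = {"threshold": grid}
    for name, vals, is_ann in (
        ("rep1", r1.to_numpy(), ann1),
        ("rep2", r2.to_numpy(), ann2),
        ("overlap", overlap_val, annb),
    ):
        size = _counts_along_grid(vals, grid)
        k = _counts_along_grid(vals[is_ann], grid) if is_ann.any() else np.zeros_like(size)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(size > 0, 100.0 * k / np.maximum(size, 1), np.nan)
        cols[f"size_{name}"] = size
        cols[f"pct_{name}"] = pct
    table = pd.DataFrame(cols)
    return ThresholdCurve(table, background_rate=100.0 * annotation.prevalence)


def select_threshold(
    curve: ThresholdCurve,
    min_enrichment: float = 40.0,
    min_overlap: int = 10,
) -> float | None:
    """Largest grid threshold whose overlap list keeps >= ``min_enrichment``
    percent annotated genes and >= ``min_overlap`` genes; None if no
    threshold qualifies."""
    if not 0.0 < min_enrichment <= 100.0:
        raise InvalidParameterError("min_enrichment must be in (0, 100]")
    t = curve.table
    ok = (t["pct_overlap"] >= min_enrichment) & (t["size_overlap"] >= min_overlap)
    if not ok.any():
        return None
    selected = float(t.loc[ok, "threshold"].max())
    curve.selected = selected
    return selected


def overlap_hits(
    ratios_rep1: pd.Series, ratios_rep2: pd.Series, threshold: float
) -> list[str]:
    """Sorted genes with ratio strictly below ``threshold`` in both repeats."""
    if threshold <= 0:
        raise InvalidParameterError("threshold must be positive")
    r1 = ratios_rep1.dropna()
    r2 = ratios_rep2.dropna()
    both = r1.index.intersection(r2.index)
    hit = (r1.loc[both] < threshold) & (r2.loc[both] < threshold)
    return sorted(both[hit])


def merge_backgrounds(*hit_lists: Iterable[str]) -> list[str]:
    """Union of hit lists from different genetic backgrounds, sorted."""
    merged: set[str] = set()
    for lst in hit_lists:
        merged |= set(lst)
    return sorted(merged)


@dataclass
class GeneSetComparison:
    """Venn partition of 2-3 named gene sets over a declared universe.

    ``region_counts`` maps a frozenset of set names to the number of genes
    belonging to exactly those sets; counts sum to the union size.
    """

    sets: dict[str, set]
    universe: set
    region_counts: dict[frozenset, int]
    n_dropped: int

    @property
    def union_size(self) -> int:
        return len(set().union(*self.sets.values())) if self.sets else 0

    def count(self, *names: str) -> int:
        """Genes in exactly the given sets (and no others)."""
        return self.region_counts.get(frozenset(names), 0)

    def as_table(self) -> pd.DataFrame:
        rows = [
            {"region": "&".join(sorted(region)), "count": count}
            for region, count in sorted(
                self.region_counts.items(), key=lambda kv: sorted(kv[0])
            )
        ]
        return pd.DataFrame(rows)


def compare_gene_sets(
    named_sets: Mapping[str, Iterable[str]], universe: Iterable[str]
) -> GeneSetComparison:
    """Full Venn partition of 2-3 gene sets restricted to ``universe``.

    Genes outside the universe are dropped (count logged); every non-empty
    exclusive region of the partition is reported.
    """
    universe = set(universe)
    if not universe:
        raise InvalidParameterError("universe must be non-empty")
    if not 2 <= len(named_sets) <= 3:
        raise InvalidParameterError("compare_gene_sets takes 2 or 3 sets")
    mapped: dict[str, set] = {}
    dropped = 0
    for name, genes in named_sets.items():
        genes = set(genes)
        inside = genes & universe
        dropped += len(genes) - len(inside)
        mapped[name] = inside
    if dropped:
        logger.info("compare_gene_sets: dropped %d gene(s) outside the universe", dropped)

    region_counts: dict[frozenset, int] = {}
    names = list(mapped)
    for gene in set().union(*mapped.values()):
        region = frozenset(n for n in names if gene in mapped[n])
        region_counts[region] = region_counts.get(region, 0) + 1
    return GeneSetComparison(mapped, universe, region_counts, dropped)
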