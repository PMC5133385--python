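"""Gene-list functional enrichment against a flat gene-set annotation.

Given a hit list drawn from a declared background (the deletion-library
gene universe) and a gene set such as GO 'mitochondrion', this module
computes the percentage of annotated genes in the list and the one-sided
hypergeometric over-representation p-value

    p = P(X >= k),  X ~ Hypergeometric(N, K, n)

with N the background size, K the annotated genes in the background, n the
list size and k the annotated genes in the list.  Multiple lists/terms are
corrected with Benjamini-Hochberg by default (Bonferroni available).  The
test is one-sided over-representation only: a respiratory screen looks for
enrichment, not depletion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import InvalidParameterError
from .types import GeneSetAnnotation


@dataclass(frozen=True)
class EnrichmentResult:
    """Over-representation of one gene set in one list."""

    list_name: str
    term: str
    k: int  # annotated in list
    n: int  # list size
    K: int  # annotated in background
    N: int  # background size
    percent: float
    p_value: float
    p_adjusted: float | None = None

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def percent_annotated(gene_list, annotation: GeneSetAnnotation) -> float:
    """Percentage of list genes carrying the annotation.

    Raises if any list gene lies outside the annotation background (a
    silent universe mismatch would bias every downstream percentage);
    an empty list gives NaN with a warning.
    """
    genes = set(gene_list)
    annotation.require_universe(genes)
    if not genes:
        warnings.warn("empty gene list: percent annotated undefined", stacklevel=2)
        return float("nan")
    k = len(genes & annotation.annotated)
    return 100.0 * k / len(genes)


def hypergeometric_enrichment(
    gene_list, annotation: GeneSetAnnotation, list_name: str = "list"
) -> EnrichmentResult:
    """One-sided hypergeometric over-representation test for one list."""
    genes = set(gene_list)
    annotation.require_universe(genes)
    N = len(annotation.background)
    K = len(annotation.annotated)
    n = len(genes)
    k = len(genes & annotation.annotated)
    if n == 0:
        warnings.warn("empty gene list: p-value degenerate at 1", stacklevel=2)
        return EnrichmentResult(list_name, annotation.set_name, 0, 0, K, N,
                                float("nan"), 1.0)
    # sf(k-1) = P(X >= k); scipy computes this via stable log-gamma terms
    p = float(hypergeom.sf(k - 1, N, K, n))
    p = min(max(p, 0.0), 1.0)
    if p == 0.0:
        p = float(np.nextafter(0, 1))  # upper tail is never exactly 0 for k <= min(n, K)
    return EnrichmentResult(
        list_name, annotation.set_name, k, n, K, N, 100.0 * k / n, p
    )


def bh_adjust(p_values, method: str = "fdr_bh") -> np.ndarray:
    """Multiple-testing adjustment (step-up Benjamini-Hochberg by default).

    ``method`` may be ``"fdr_bh"`` or ``"bonferroni"``.  Order-preserving;
    adjusted values are capped at 1.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise InvalidParameterError("p-values must lie in [0, 1]")
    if method not in ("fdr_bh", "bonferroni"):
        raise InvalidParameterError(f"unknown adjustment method {method!r}")
    return multipletests(p, method=method)[1]


def enrichment_table(
    named_lists: dict[str, list],
    annotation: GeneSetAnnotation,
    method: str = "fdr_bh",
) -> pd.DataFrame:
    """Test several gene lists against one annotation; adjust across lists."""
    results = [
        hypergeometric_enrichment(genes, annotation, list_name=name)
        for name, genes in named_lists.items()
    ]
    adj = bh_adjust([r.p_value for r in results], method=method)
    rows = []
    for r, a in zip(results, adj):
        d = r.as_dict()
        d["p_adjusted"] = float(a)
        rows.append(d)
    return pd.DataFrame(rows)


def top_n_hits(ratios: pd.Series, n: int = 100) -> list[str]:
    """The ``n`` genes with the smallest (unfiltered) colony-size ratios.

    ``ratios`` is gene-indexed; NaN entries (filtered genes) are excluded.
    Ties at the boundary break by lexicographic gene ID.  If fewer than
    ``n`` ratios exist, all are returned with a warning.
    """
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    clean = ratios.dropna()
    order = sorted(clean.items(), key=lambda kv: (kv[1], kv[0]))
    if len(order) < n:
        warnings.warn(
            f"only {len(order)} unfiltered ratios available (< {n}); returning all",
            stacklevel=2,
        )
    return [g for g, _ in order[:n]]
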