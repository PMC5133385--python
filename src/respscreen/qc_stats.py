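"""Dataset-level validation: replicate correlations and hierarchical clustering.

The 16 datasets of a screen (2 backgrounds x 2 media x 2 biological x 2
technical repeats) are compared as gene vectors of normalized colony sizes.
Pairwise Pearson correlations use pairwise-complete observations; clustering
uses Euclidean distances over complete-case genes with Ward agglomeration in
the convention that applies the Ward (Lance-Williams) update directly to the
*unsquared* input distances — the behaviour of R's ``hclust(method =
"ward.D")`` — with the squared-distance convention ("ward.D2") available as
an option.

In a well-behaved screen, technical repeats of the same biological repeat
correlate most strongly and appear as sibling leaves of the dendrogram,
while biological repeats correlate more weakly.
"""

from __future__ import annotations

import itertools
import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .errors import EmptyPlateError, InvalidParameterError


def dataset_matrix(long_df: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long screen table into genes x datasets of normalized sizes.

    Column labels follow ``<background>_<medium>_b<B>_t<T>``; missing
    colonies stay NaN.
    """
    df = long_df.copy()
    df["dataset"] = (
        df["background"].astype(str) + "_" + df["medium"].astype(str)
        + "_b" + df["bio_repeat"].astype(str) + "_t" + df["tech_repeat"].astype(str)
    )
    return df.pivot(index="gene", columns="dataset", values="value").sort_index(axis=1)


def correlation_matrix(matrix: pd.DataFrame, min_overlap: int = 3) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations between dataset columns.

    Pairs with fewer than ``min_overlap`` complete genes give NaN (with a
    warning); the diagonal is exactly 1.
    """
    if matrix.shape[1] < 2:
        raise InvalidParameterError("need at least 2 dataset columns")
    corr = matrix.corr(method="pearson", min_periods=min_overlap)
    np.fill_diagonal(corr.values, 1.0)
    off_diag_na = corr.isna().to_numpy().sum()
    if off_diag_na:
        warnings.warn(
            f"{off_diag_na // 2} dataset pair(s) have < {min_overlap} "
            "pairwise-complete genes; correlation set missing",
            stacklevel=2,
        )
    return corr


@dataclass
class ClusterResult:
    """Agglomeration of dataset columns.

    ``labels`` are the leaf names (sorted; leaf i in ``merges`` refers to
    ``labels[i]``); ``merges`` is an (n-1, 2) array in scipy convention
    (cluster n-1+k is formed at merge k); ``heights`` the merge criteria.
    """

    labels: list[str]
    merges: np.ndarray
    heights: np.ndarray
    method: str

    @property
    def linkage(self) -> np.ndarray:
        """Scipy-style linkage matrix (merge heights monotone for Ward)."""
        n = len(self.labels)
        counts = np.zeros(n - 1)
        sizes = {i: 1 for i in range(n)}
        for k, (a, b) in enumerate(self.merges):
            sizes[n + k] = sizes[int(a)] + sizes[int(b)]
            counts[k] = sizes[n + k]
        return np.column_stack(
            [self.merges.astype(float), self.heights, counts]
        )

    def leaf_cherries(self) -> set[frozenset]:
        """Label pairs that merge as two singleton leaves ('cherries')."""
        n = len(self.labels)
        out = set()
        for a, b in self.merges:
            if a < n and b < n:
                out.add(frozenset({self.labels[int(a)], self.labels[int(b)]}))
        return out

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def rec(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            left, right = rec(node.left), rec(node.right)
            return f"({left},{right}):{node.dist:.6g}"

        return rec(tree).rsplit(":", 1)[0] + ";"


def cluster_datasets(matrix: pd.DataFrame, method: str = "ward.D") -> ClusterResult:
    """Ward clustering of dataset columns on Euclidean distances.

    Genes missing in any dataset are dropped (complete case).  With
    ``method="ward.D"`` the Ward update runs on the raw Euclidean distances;
    ``"ward.D2"`` runs it on squared distances (reporting square-rooted
    heights), which is also the behaviour of clustering the raw columns.
    """
    if method not in ("ward.D", "ward.D2"):
        raise InvalidParameterError(f"unknown clustering method {method!r}")
    complete = matrix.dropna(axis=0, how="any")
    if complete.shape[0] == 0:
        raise EmptyPlateError(
            "no gene is complete across all datasets; relax missingness first"
        )
    complete = complete.sort_index(axis=1)
    labels = list(complete.columns)
    dist = pdist(complete.to_numpy().T, metric="euclidean")
    if method == "ward.D":
        # scipy's 'ward' applies the Lance-Williams update to squared input
        # distances and reports sqrt; feeding sqrt(d) and squaring heights
        # is algebraically the plain-Ward update on the unsquared d.
        z = hierarchy.linkage(np.sqrt(dist), method="ward")
        heights = z[:, 2] ** 2
    else:
        z = hierarchy.linkage(dist, method="ward")
        heights = z[:, 2]
    return ClusterResult(labels, z[:, :2].astype(int), heights, method)


_LABEL_RE = re.compile(r"^(?P<bg>[a-z]+)_(?P<med>[a-z]+)_b(?P<b>\d+)_t(?P<t>\d+)$")


def _parse_label(label: str) -> tuple[str, str, int, int]:
    m = _LABEL_RE.match(label)
    if not m:
        raise InvalidParameterError(f"unparseable dataset label {label!r}")
    return m["bg"], m["med"], int(m["b"]), int(m["t"])


def replicate_concordance(corr: pd.DataFrame) -> dict[str, float]:
    """Mean correlation within technical-repeat pairs vs between biological repeats.

    Technical pairs share background, medium and biological repeat;
    biological pairs share background and medium but differ in biological
    repeat (any technical repeat).
    """
    labels = list(corr.columns)
    parsed = {lab: _parse_label(lab) for lab in labels}
    tech, bio = [], []
    for a, b in itertools.combinations(labels, 2):
        pa, pb = parsed[a], parsed[b]
        r = corr.loc[a, b]
        if np.isnan(r):
            continue
        if pa[:3] == pb[:3] and pa[3] != pb[3]:
            tech.append(r)
        elif pa[:2] == pb[:2] and pa[2] != pb[2]:
            bio.append(r)
    return {
        "mean_r_within_technical": float(np.mean(tech)) if tech else float("nan"),
        "mean_r_between_biological": float(np.mean(bio)) if bio else float("nan"),
        "n_technical_pairs": len(tech),
        "n_biological_pairs": len(bio),
    }
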