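"""From normalized plates to per-gene ratio phenotypes.

Technical repeats (replicate platings from the same template) are averaged;
biological repeats (independent platings from frozen stock) are kept
separate throughout because they vary far more.  Three quality filters are
applied per (gene, background, medium, biological repeat) before ratios are
formed:

* ``high_se`` — standard error across technical repeats > ``se_max``
  (default 0.4; with two repeats x1, x2 the SE is |x1 - x2| / 2);
* ``absent_in_repeat`` — the colony is missing in at least one technical
  repeat;
* ``small_on_glucose`` — mean normalized glucose size < ``min_glucose``
  (default 0.12): a strain that barely grows on the control medium gives a
  meaningless, explosive ratio.

Both thresholds are strict inequalities: SE exactly 0.4 and glucose size
exactly 0.12 pass.  The phenotype is the colony-size ratio
glycerol / glucose per biological repeat; a ratio well below 1 marks a
respiratory-deficient strain.  Ratios are never averaged across biological
repeats.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .types import DatasetKey, LibraryLayout, PlateGrid

SUMMARY_INDEX = ["gene", "background", "medium", "bio_repeat"]
RATIO_INDEX = ["gene", "background", "bio_repeat"]


def screen_long_table(
    grids: Mapping[DatasetKey, PlateGrid], layout: LibraryLayout
) -> pd.DataFrame:
    """Flatten a screen's plate grids into one long table.

    Columns: gene, background, medium, bio_repeat, tech_repeat, value
    (NaN where the colony is missing).  One row per gene per dataset.
    """
    records = []
    gene_grids = {p: layout.gene_grid(p) for p in layout.plate_ids}
    for key in sorted(grids, key=lambda k: k.label):
        grid = grids[key]
        ggrid = gene_grids[int(key.plate_id)]
        for (i, j), gene in np.ndenumerate(ggrid):
            if gene is None:
                continue
            value = np.nan if grid.missing[i, j] else grid.sizes[i, j]
            records.append(
                (gene, key.background, key.medium, key.bio_repeat,
                 key.tech_repeat, value)
            )
    return pd.DataFrame(
        records,
        columns=["gene", "background", "medium", "bio_repeat", "tech_repeat", "value"],
    )


def summarize_technical(values: Sequence[float]) -> tuple[float, float, int]:
    """Mean, standard error and count over present technical-repeat values.

    Missing values are NaN.  SE is the sample standard deviation divided by
    sqrt(n) (0 when n = 1; for n = 2 this equals |x1 - x2| / 2); an
    all-missing input yields (nan, nan, 0).
    """
    arr = np.asarray(values, dtype=float)
    present = arr[~np.isnan(arr)]
    n = present.size
    if n == 0:
        return (float("nan"), float("nan"), 0)
    mean = float(present.mean())
    se = 0.0 if n == 1 else float(present.std(ddof=1) / np.sqrt(n))
    return (mean, se, n)


def summarize_technical_table(long_df: pd.DataFrame) -> pd.DataFrame:
    """Collapse technical repeats: one row per (gene, background, medium, bio_repeat).

    Output columns: mean, se, n_present, n_tech_expected.
    """
    grouped = long_df.groupby(SUMMARY_INDEX, sort=True)["value"]
    mean = grouped.mean()
    n_present = grouped.count()
    n_expected = grouped.size()
    sd = grouped.std(ddof=1)
    se = (sd / np.sqrt(n_present)).where(n_present > 1, 0.0)
    se = se.where(n_present > 0, np.nan)
    out = pd.DataFrame(
        {
            "mean": mean,
            "se": se,
            "n_present": n_present.astype(int),
            "n_tech_expected": n_expected.astype(int),
        }
    ).reset_index()
    return out


def apply_qc_filters(
    summary: pd.DataFrame, se_max: float = 0.4, min_glucose: float = 0.12
) -> pd.DataFrame:
    """Flag unreliable technical-repeat summaries (strict thresholds).

    Adds boolean columns ``high_se``, ``absent_in_repeat``,
    ``small_on_glucose`` and their union ``filtered``.
    """
    out = summary.copy()
    out["high_se"] = out["se"] > se_max
    out["absent_in_repeat"] = out["n_present"] < out["n_tech_expected"]
    out["small_on_glucose"] = (out["medium"] == "glucose") & (out["mean"] < min_glucose)
    out["filtered"] = out[["high_se", "absent_in_repeat", "small_on_glucose"]].any(axis=1)
    return out


def qc_flag_counts(summary: pd.DataFrame) -> dict[str, int]:
    """Number of (gene, background, medium, bio_repeat) entries per flag."""
    return {
        flag: int(summary[flag].sum())
        for flag in ("high_se", "absent_in_repeat", "small_on_glucose", "filtered")
    }


def compute_ratios(summary: pd.DataFrame) -> pd.DataFrame:
    """Glycerol/glucose colony-size ratio per (gene, background, bio_repeat).

    A ratio exists only when both media pass QC for that gene, background
    and biological repeat; ratios are deliberately not averaged across
    biological repeats.  Output columns: ratio (NaN if filtered), filtered.
    """
    if "filtered" not in summary.columns:
        summary = apply_qc_filters(summary)
    wide = (
        summary.set_index(RATIO_INDEX + ["medium"])[["mean", "filtered"]]
        .unstack("medium")
    )
    for medium in ("glucose", "glycerol"):
        if ("mean", medium) not in wide.columns:
            raise KeyError("summary must contain both glucose and glycerol entries")
    gluc_mean = wide[("mean", "glucose")]
    glyc_mean = wide[("mean", "glycerol")]
    gluc_filt = wide[("filtered", "glucose")]
    glyc_filt = wide[("filtered", "glycerol")]
    ok = (
        ~gluc_filt.fillna(True).astype(bool)
        & ~glyc_filt.fillna(True).astype(bool)
        & gluc_mean.notna()
        & glyc_mean.notna()
    )
    zero_gluc = ok & (gluc_mean <= 0)
    if zero_gluc.any():
        warnings.warn(
            f"{int(zero_gluc.sum())} unfiltered entries have zero glucose mean; "
            "their ratios are set missing",
            stacklevel=2,
        )
        ok &= ~zero_gluc
    ratio = (glyc_mean / gluc_mean).where(ok)
    out = pd.DataFrame({"ratio": ratio, "filtered": ~ok}).reset_index()
    return out


def ratios_for(
    ratio_table: pd.DataFrame, background: str, bio_repeat: int
) -> pd.Series:
    """Gene-indexed ratio series for one background and biological repeat
    (filtered genes carry NaN)."""
    sub = ratio_table[
        (ratio_table["background"] == background)
        & (ratio_table["bio_repeat"] == bio_repeat)
    ]
    return sub.set_index("gene")["ratio"].sort_index()
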