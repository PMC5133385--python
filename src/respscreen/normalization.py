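"""Plate-level normalization of raw colony sizes.

Raw colony areas mix the biological signal (strain fitness) with several
technical artefacts: plate-to-plate scale differences, inflated growth in
border rows/columns ("edge effects"), and smooth local variations of the
agar surface.  All corrections are multiplicative — colony areas are
positive and scans differ by scale factors — and each step is exposed
separately:

1. :func:`flag_absent` — mask non-grown colonies (size 0) and empty layout
   positions so they never enter a statistic;
2. :func:`normalize_plate_median` — divide by the plate median, making
   plates comparable (median becomes 1);
3. :func:`correct_row_col` — divide each row by its median, then each
   column of the result by its median, removing separable row/column
   artefacts such as edge effects;
4. :func:`median_spatial_filter` — divide each colony by the median of its
   window x window neighborhood, removing smooth local artefacts while
   preserving isolated true effects (a single deviating colony is its own
   neighborhood's outlier, not its median).

:func:`normalize_plate` composes the four in that order.  Every step is
scale-free, and every post-raw stage leaves the non-missing plate median at
exactly 1 (steps 3-4 end with an explicit rescale to keep this invariant).

Medians of even-length samples are the midpoint of the two central order
statistics.  Rows, columns or neighborhoods with fewer than ``min_count``
non-missing entries yield a correction factor of 1 (an unstable median is
worse than no correction).
"""

from __future__ import annotations

import numpy as np

from .errors import EmptyPlateError, InvalidParameterError
from .types import PlateGrid


def _require_stage(grid: PlateGrid, stage: str, op: str) -> None:
    if grid.stage != stage:
        raise InvalidParameterError(
            f"{op} expects a grid at stage {stage!r}, got {grid.stage!r}"
        )


def _masked_median(values: np.ndarray, missing: np.ndarray) -> float:
    vals = values[~missing]
    if vals.size == 0:
        raise EmptyPlateError("plate has no non-missing colonies")
    return float(np.median(vals))


def flag_absent(grid: PlateGrid, layout_empty: np.ndarray | None = None) -> PlateGrid:
    """Mask absent colonies (size 0) and layout-empty positions.

    Sizes are unchanged; only the missing-mask grows.  Stage stays ``raw``.
    """
    _require_stage(grid, "raw", "flag_absent")
    out = grid.copy()
    out.missing |= out.sizes == 0.0
    if layout_empty is not None:
        out.missing |= np.asarray(layout_empty, dtype=bool)
    return out


def normalize_plate_median(grid: PlateGrid) -> PlateGrid:
    """Divide every non-missing size by the plate's non-missing median."""
    _require_stage(grid, "raw", "normalize_plate_median")
    out = grid.copy()
    med = _masked_median(out.sizes, out.missing)
    if med <= 0:
        raise EmptyPlateError("plate median is zero; nothing to normalize")
    out.sizes = out.sizes / med
    out.sizes[out.missing] = 0.0
    out.stage = "median_normalized"
    return out


def _line_factors(
    sizes: np.ndarray, missing: np.ndarray, axis: int, min_count: int
) -> np.ndarray:
    """Per-row (axis=1) or per-column (axis=0) median factors; 1 where sparse."""
    # iterate lines explicitly: masked medians are irregular-length
    n_lines = sizes.shape[0] if axis == 1 else sizes.shape[1]
    factors = np.ones(n_lines)
    for i in range(n_lines):
        line = sizes[i, :] if axis == 1 else sizes[:, i]
        mask = missing[i, :] if axis == 1 else missing[:, i]
        vals = line[~mask]
        if vals.size >= min_count:
            med = float(np.median(vals))
            if med > 0:
                factors[i] = med
    return factors


def correct_row_col(
    grid: PlateGrid, min_count: int = 3, polish_iterations: int = 1
) -> PlateGrid:
    """Remove row- and column-specific artefacts by median division.

    Each row is divided by its non-missing median, then each column of the
    result by its median; ``polish_iterations`` > 1 repeats the alternating
    pass (a separable row x column profile is removed exactly in one pass on
    a complete grid).  The plate is rescaled to non-missing median 1 at the
    end.
    """
    _require_stage(grid, "median_normalized", "correct_row_col")
    if polish_iterations < 1:
        raise InvalidParameterError("polish_iterations must be >= 1")
    out = grid.copy()
    if (~out.missing).sum() == 0:
        raise EmptyPlateError("plate has no non-missing colonies")
    for _ in range(polish_iterations):
        row_f = _line_factors(out.sizes, out.missing, axis=1, min_count=min_count)
        out.sizes = out.sizes / row_f[:, None]
        col_f = _line_factors(out.sizes, out.missing, axis=0, min_count=min_count)
        out.sizes = out.sizes / col_f[None, :]
    out.sizes = out.sizes / _masked_median(out.sizes, out.missing)
    out.sizes[out.missing] = 0.0
    out.stage = "rowcol_corrected"
    return out


def median_spatial_filter(
    grid: PlateGrid, window: int = 3, min_count: int = 3
) -> PlateGrid:
    """Divide each colony by its local neighborhood median.

    The neighborhood is the ``window x window`` block centred on the
    position (center included), truncated at plate borders; only non-missing
    entries contribute.  Neighborhoods with fewer than ``min_count``
    non-missing entries give factor 1; a position whose neighborhood is
    entirely missing is itself set missing.  The plate is rescaled to
    non-missing median 1 afterwards.
    """
    _require_stage(grid, "rowcol_corrected", "median_spatial_filter")
    if window < 3 or window % 2 == 0:
        raise InvalidParameterError("window must be an odd integer >= 3")
    out = grid.copy()
    rows, cols = out.shape
    half = window // 2
    corrected = out.sizes.copy()
    for i in range(rows):
        i0, i1 = max(0, i - half), min(rows, i + half + 1)
        for j in range(cols):
            if out.missing[i, j]:
                continue
            j0, j1 = max(0, j - half), min(cols, j + half + 1)
            block = out.sizes[i0:i1, j0:j1]
            bmask = out.missing[i0:i1, j0:j1]
            vals = block[~bmask]
            if vals.size == 0:
                out.missing[i, j] = True
                corrected[i, j] = 0.0
                continue
            if vals.size < min_count:
                continue
            m = float(np.median(vals))
            if m > 0:
                corrected[i, j] = out.sizes[i, j] / m
    out.sizes = corrected
    out.sizes = out.sizes / _masked_median(out.sizes, out.missing)
    out.sizes[out.missing] = 0.0
    out.stage = "spatially_corrected"
    return out


def normalize_plate(
    grid: PlateGrid,
    layout_empty: np.ndarray | None = None,
    window: int = 3,
    min_count: int = 3,
    polish_iterations: int = 1,
) -> PlateGrid:
    """Full per-plate normalization: mask absents, median-normalize, remove
    row/column artefacts, apply the local median filter."""
    g = flag_absent(grid, layout_empty=layout_empty)
    g = normalize_plate_median(g)
    g = correct_row_col(g, min_count=min_count, polish_iterations=polish_iterations)
    g = median_spatial_filter(g, window=window, min_count=min_count)
    return g
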