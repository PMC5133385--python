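import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import respscreen as rs
from respscreen.errors import EmptyPlateError, InvalidParameterError
from respscreen.normalization import (
    correct_row_col,
    flag_absent,
    median_spatial_filter,
    normalize_plate,
    normalize_plate_median,
)

from conftest import make_grid, noise_free_params


# ------------------------------------------------------------- flag_absent


def test_flag_absent_masks_zero_sizes_and_layout_empties():
    sizes = np.full((4, 4), 2.0)
    sizes[0, 0] = sizes[1, 2] = sizes[3, 3] = 0.0
    empty = np.zeros((4, 4), dtype=bool)
    empty[2, 2] = True
    out = flag_absent(make_grid(sizes), layout_empty=empty)
    expected = (sizes == 0) | empty
    assert np.array_equal(out.missing, expected)
    assert np.array_equal(out.sizes, sizes)


def test_flag_absent_all_positive_masks_only_empties():
    out = flag_absent(make_grid(np.full((3, 3), 1.0)))
    assert out.n_missing == 0


def test_all_zero_plate_raises_downstream():
    g = flag_absent(make_grid(np.zeros((3, 3))))
    with pytest.raises(EmptyPlateError):
        normalize_plate_median(g)


# ------------------------------------------------- normalize_plate_median


def test_median_normalization_uniform_plate():
    out = normalize_plate_median(make_grid(np.full((4, 6), 42.0)))
    assert np.allclose(out.present_values(), 1.0)
    assert out.stage == "median_normalized"


def test_median_normalization_known_values():
    sizes = np.zeros((1, 7))
    sizes[0, :5] = [2, 4, 6, 8, 10]
    missing = np.zeros((1, 7), dtype=bool)
    missing[0, 5:] = True
    out = normalize_plate_median(make_grid(sizes, missing))
    assert np.allclose(out.sizes[0, :5], [1 / 3, 2 / 3, 1.0, 4 / 3, 5 / 3])


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    hnp.arrays(
        float,
        (6, 8),
        elements=st.floats(min_value=0.01, max_value=1e4,
                           allow_nan=False, allow_infinity=False),
    )
)
def test_median_normalization_matches_one_line_oracle(sizes):
    out = normalize_plate_median(make_grid(sizes))
    assert np.median(out.present_values()) == pytest.approx(1.0, abs=1e-9)
    assert np.allclose(out.sizes, sizes / np.median(sizes))


# ---------------------------------------------------------- correct_row_col


def _to_rowcol_input(sizes, missing=None):
    return normalize_plate_median(make_grid(sizes, missing))


def test_rowcol_uniform_plate_unchanged():
    out = correct_row_col(_to_rowcol_input(np.full((6, 8), 3.0)))
    assert np.allclose(out.present_values(), 1.0)


def test_rowcol_constant_rows_flatten_after_row_pass():
    k = np.array([1.0, 2.0, 3.0, 4.0])
    sizes = np.tile(k[:, None], (1, 8))
    out = correct_row_col(_to_rowcol_input(sizes))
    assert np.allclose(out.present_values(), 1.0, atol=1e-12)


def test_rowcol_removes_separable_profile_exactly():
    rng = np.random.default_rng(5)
    r = rng.uniform(0.5, 2.0, 10)
    c = rng.uniform(0.5, 2.0, 14)
    sizes = 37.0 * np.outer(r, c)
    out = correct_row_col(_to_rowcol_input(sizes))
    assert np.allclose(out.present_values(), 1.0, atol=1e-9)
    # row medians 1 after the row pass, column medians 1 after the column pass
    assert np.allclose(np.median(out.sizes, axis=0), 1.0, atol=1e-9)


def test_rowcol_sparse_rows_left_uncorrected():
    sizes = np.full((4, 6), 1.0)
    missing = np.zeros((4, 6), dtype=bool)
    missing[0, :4] = True  # row 0 has 2 entries < min_count
    sizes[0, 4:] = 5.0
    out = correct_row_col(_to_rowcol_input(sizes, missing), min_count=3)
    # the 5s survive: their row median was not used as a divisor
    assert np.allclose(out.sizes[0, 4:], 5.0)


def test_rowcol_requires_median_normalized_stage(uniform_grid):
    with pytest.raises(InvalidParameterError, match="stage"):
        correct_row_col(uniform_grid)


# ---------------------------------------------------- median_spatial_filter


def _to_filter_input(sizes, missing=None):
    return correct_row_col(_to_rowcol_input(sizes, missing))


def _dense_window_median_oracle(sizes, missing, window):
    """Independent recomputation of truncated windowed medians."""
    rows, cols = sizes.shape
    half = window // 2
    med = np.ones_like(sizes)
    for i in range(rows):
        for j in range(cols):
            vals = [
                sizes[a, b]
                for a in range(max(0, i - half), min(rows, i + half + 1))
                for b in range(max(0, j - half), min(cols, j + half + 1))
                if not missing[a, b]
            ]
            if len(vals) >= 3:
                med[i, j] = np.median(vals)
    return med


def test_filter_uniform_plate_unchanged():
    out = median_spatial_filter(_to_filter_input(np.full((6, 8), 2.0)))
    assert np.allclose(out.present_values(), 1.0)


def test_filter_preserves_isolated_outlier_exactly():
    sizes = np.full((8, 12), 1.0)
    sizes[4, 6] = 5.0
    grid = make_grid(sizes, stage="rowcol_corrected")
    out = median_spatial_filter(grid, window=3)
    assert out.sizes[4, 6] == pytest.approx(5.0)
    rest = out.sizes[~out.missing].copy().reshape(8, 12)
    rest[4, 6] = 1.0
    assert np.allclose(rest, 1.0)


def test_filter_rejects_even_window(uniform_grid):
    grid = make_grid(np.full((4, 4), 1.0), stage="rowcol_corrected")
    with pytest.raises(InvalidParameterError):
        median_spatial_filter(grid, window=4)


def test_filter_flattens_smooth_bump():
    # Gaussian bump, amplitude 1.5, sigma much larger than the window
    rows, cols = 16, 24
    ii, jj = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    bump = 1.0 + 1.5 * np.exp(-((ii - 8.0) ** 2 + (jj - 12.0) ** 2) / (2 * 6.0**2))
    grid = make_grid(bump, stage="rowcol_corrected")
    out = median_spatial_filter(grid, window=3)
    interior = out.sizes[1:-1, 1:-1]
    assert np.all(np.abs(interior - 1.0) < 0.05)


def test_filter_matches_dense_median_oracle():
    rng = np.random.default_rng(8)
    sizes = rng.lognormal(0, 0.3, (8, 12))
    missing = rng.random((8, 12)) < 0.1
    sizes[missing] = 0.0
    grid = make_grid(sizes, missing, stage="rowcol_corrected")
    out = median_spatial_filter(grid, window=3)
    med = _dense_window_median_oracle(sizes, missing, 3)
    expected = np.where(missing, 0.0, sizes / med)
    scale = np.median(expected[~missing])
    assert np.allclose(out.sizes[~missing], (expected / scale)[~missing], atol=1e-9)


# ------------------------------------------------------------ normalize_plate


def test_normalize_plate_removes_generator_artefacts_within_5pct():
    params = noise_free_params(
        n_genes=384, grid_rows=16, grid_cols=24,
        edge_effect_strength=0.3, spatial_blob_count=1,
        spatial_blob_amplitude=0.5, seed=3,
    )
    layout = rs.generate_layout(384, 16, 24, seed=3)
    ann = rs.generate_annotation(layout, 0.13, seed=3)
    grids, _ = rs.simulate_screen(layout, ann, params)
    for grid in list(grids.values())[:2]:
        # plate effect enters via the lognormal scale; impose one manually too
        scaled = make_grid(grid.sizes * 2.0, grid.missing)
        out = normalize_plate(scaled)
        assert np.all(np.abs(out.present_values() - 1.0) < 0.05)


@pytest.mark.parametrize("alpha", [0.1, 3.0, 100.0])
def test_normalize_plate_scale_invariance(alpha):
    rng = np.random.default_rng(12)
    sizes = rng.lognormal(3, 0.5, (16, 24))
    missing = rng.random((16, 24)) < 0.05
    sizes[missing] = 0.0
    base = normalize_plate(make_grid(sizes, missing))
    scaled = normalize_plate(make_grid(alpha * sizes, missing))
    assert np.allclose(base.sizes, scaled.sizes, rtol=1e-9)
    assert np.array_equal(base.missing, scaled.missing)


def test_normalize_plate_median_one_at_every_stage():
    rng = np.random.default_rng(13)
    sizes = rng.lognormal(3, 0.4, (16, 24))
    g = flag_absent(make_grid(sizes))
    g = normalize_plate_median(g)
    assert np.median(g.present_values()) == pytest.approx(1.0, abs=1e-9)
    g = correct_row_col(g)
    assert np.median(g.present_values()) == pytest.approx(1.0, abs=1e-9)
    g = median_spatial_filter(g)
    assert np.median(g.present_values()) == pytest.approx(1.0, abs=1e-9)


def test_normalize_plate_keeps_deficient_signal():
    # spatially isolated deficient colonies at multiplier 0.5 survive the
    # full normalization: those positions ~0.5, all others ~1 (the median
    # filter only guarantees preservation of isolated deviations)
    deficient = np.zeros((16, 24), dtype=bool)
    deficient[::4, ::4] = True
    sizes = 2.0 * np.where(deficient, 0.5, 1.0)
    sizes *= np.outer(  # separable edge artefact on top
        np.where(np.isin(np.arange(16), [0, 15]), 1.3, 1.0),
        np.where(np.isin(np.arange(24), [0, 23]), 1.3, 1.0),
    )
    out = normalize_plate(make_grid(sizes))
    expected = np.where(deficient, 0.5, 1.0)
    assert np.allclose(out.sizes, expected, rtol=0.02)
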