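"""Core in-memory containers shared by every pipeline stage.

The pipeline's unit of raw data is a :class:`PlateGrid` — one arrayed agar
plate, scanned under one condition for one repeat — holding a rectangular
matrix of colony sizes plus a mask of missing (non-grown or empty) positions.
A :class:`LibraryLayout` maps grid positions to deletion-strain gene IDs and
thereby defines the screen's gene universe; a :class:`GeneSetAnnotation`
records membership of those genes in a named functional gene set (typically
the GO cellular-component term 'mitochondrion', GO:0005739).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ConsistencyError, InvalidParameterError, LayoutError

BACKGROUNDS = ("auxotroph", "prototroph")
MEDIA = ("glucose", "glycerol")

#: Normalization stages, in pipeline order.
STAGES = ("raw", "median_normalized", "rowcol_corrected", "spatially_corrected")

#: Reserved token for an unoccupied grid position in layout tables.
EMPTY_TOKEN = "EMPTY"


@dataclass(frozen=True)
class DatasetKey:
    """Identity of one dataset: which library, medium and repeat it came from.

    A full screen enumerates 2 backgrounds x 2 media x 2 biological x 2
    technical repeats = 16 datasets, each spanning one set of plates.
    """

    background: str
    medium: str
    bio_repeat: int
    tech_repeat: int
    plate_id: str = ""

    def __post_init__(self) -> None:
        if self.background not in BACKGROUNDS:
            raise InvalidParameterError(f"unknown background {self.background!r}")
        if self.medium not in MEDIA:
            raise InvalidParameterError(f"unknown medium {self.medium!r}")

    @property
    def dataset_label(self) -> str:
        """Label identifying the dataset (plate omitted), e.g. ``auxotroph_glucose_b1_t2``."""
        return f"{self.background}_{self.medium}_b{self.bio_repeat}_t{self.tech_repeat}"

    @property
    def label(self) -> str:
        if self.plate_id:
            return f"{self.dataset_label}_p{self.plate_id}"
        return self.dataset_label

    def with_plate(self, plate_id: str) -> "DatasetKey":
        return replace(self, plate_id=str(plate_id))


def enumerate_dataset_keys(
    n_bio: int = 2, n_tech: int = 2
) -> list[DatasetKey]:
    """All dataset keys of a screen, in a fixed canonical order."""
    return [
        DatasetKey(bg, med, b, t)
        for bg in BACKGROUNDS
        for med in MEDIA
        for b in range(1, n_bio + 1)
        for t in range(1, n_tech + 1)
    ]


@dataclass
class PlateGrid:
    """One plate's colony sizes on a rectangular grid, with a missing-mask.

    ``sizes`` holds nonnegative colony areas (gitter pixel units for raw
    plates, dimensionless after normalization).  ``missing`` marks positions
    excluded from every statistic: empty layout positions and colonies that
    failed to grow (size 0).  ``stage`` tracks progress through the
    normalization pipeline (see :data:`STAGES`).
    """

    sizes: np.ndarray
    missing: np.ndarray
    key: DatasetKey | None = None
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.sizes.ndim != 2:
            raise InvalidParameterError("sizes must be a 2-D matrix")
        if self.missing.shape != self.sizes.shape:
            raise InvalidParameterError("missing mask shape differs from sizes")
        if self.stage not in STAGES:
            raise InvalidParameterError(f"unknown stage {self.stage!r}")
        present = self.sizes[~self.missing]
        if present.size and (present < 0).any():
            raise InvalidParameterError("colony sizes must be nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.sizes.shape

    @property
    def n_missing(self) -> int:
        return int(self.missing.sum())

    def present_values(self) -> np.ndarray:
        """Sizes of non-missing positions, flattened."""
        return self.sizes[~self.missing]

    def median(self) -> float:
        """Median over non-missing positions."""
        vals = self.present_values()
        if vals.size == 0:
            from .errors import EmptyPlateError

            raise EmptyPlateError("plate has no non-missing colonies")
        return float(np.median(vals))

    def copy(self) -> "PlateGrid":
        return PlateGrid(
            self.sizes.copy(), self.missing.copy(), key=self.key, stage=self.stage
        )


class LibraryLayout:
    """Mapping from (plate, row, col) grid positions to deletion-strain genes.

    Rows/columns are 1-based with row 1 at the top-left, matching the colony
    quantitation convention.  Every gene occupies exactly one position;
    positions without a strain are *empty* and are masked on every plate of
    every dataset.
    """

    def __init__(self, table: pd.DataFrame, grid_rows: int, grid_cols: int):
        required = {"plate", "row", "col", "gene"}
        if not required.issubset(table.columns):
            raise LayoutError(f"layout table must have columns {sorted(required)}")
        if grid_rows < 1 or grid_cols < 1:
            raise InvalidParameterError("grid dimensions must be positive")
        table = table.loc[:, ["plate", "row", "col", "gene"]].copy()
        table["plate"] = table["plate"].astype(int)
        table["row"] = table["row"].astype(int)
        table["col"] = table["col"].astype(int)
        table["gene"] = table["gene"].astype(str)

        occupied = table[table["gene"] != EMPTY_TOKEN]
        dup_genes = occupied["gene"][occupied["gene"].duplicated()]
        if len(dup_genes):
            raise LayoutError(f"gene mapped to two positions: {dup_genes.iloc[0]}")
        pos = table[["plate", "row", "col"]]
        if pos.duplicated().any():
            raise LayoutError("duplicate (plate, row, col) position in layout")
        bad = (
            (table["row"] < 1)
            | (table["row"] > grid_rows)
            | (table["col"] < 1)
            | (table["col"] > grid_cols)
        )
        if bad.any():
            raise LayoutError("layout position outside the declared grid")

        self.table = table.reset_index(drop=True)
        self.grid_rows = int(grid_rows)
        self.grid_cols = int(grid_cols)
        self._occupied = occupied.reset_index(drop=True)
        self._by_gene = {
            g: (int(p), int(r), int(c))
            for p, r, c, g in self._occupied.itertuples(index=False)
        }

    @property
    def genes(self) -> list[str]:
        """Gene universe (sorted)."""
        return sorted(self._by_gene)

    @property
    def n_genes(self) -> int:
        return len(self._by_gene)

    @property
    def n_plates(self) -> int:
        return int(self.table["plate"].max())

    @property
    def plate_ids(self) -> list[int]:
        return sorted(self.table["plate"].unique())

    def position_of(self, gene: str) -> tuple[int, int, int]:
        """(plate, row, col) of a gene's strain."""
        return self._by_gene[gene]

    def empty_mask(self, plate: int) -> np.ndarray:
        """Boolean grid marking positions with no strain on ``plate``."""
        mask = np.ones((self.grid_rows, self.grid_cols), dtype=bool)
        sub = self._occupied[self._occupied["plate"] == plate]
        mask[sub["row"].to_numpy() - 1, sub["col"].to_numpy() - 1] = False
        return mask

    def gene_grid(self, plate: int) -> np.ndarray:
        """Object grid of gene IDs for ``plate`` (None where empty)."""
        grid = np.full((self.grid_rows, self.grid_cols), None, dtype=object)
        sub = self._occupied[self._occupied["plate"] == plate]
        for _, r, c, g in sub.itertuples(index=False):
            grid[r - 1, c - 1] = g
        return grid

    def n_empty_positions(self) -> int:
        return self.n_plates * self.grid_rows * self.grid_cols - self.n_genes


class GeneSetAnnotation:
    """Membership of genes in one named gene set, over a declared background.

    Genes annotated but absent from the background are retained in
    ``annotated_raw`` yet excluded from every enrichment computation (the
    background defines the statistical universe).
    """

    def __init__(self, set_name: str, annotated: Iterable[str], background: Iterable[str]):
        self.set_name = str(set_name)
        self.background = frozenset(background)
        self.annotated_raw = frozenset(annotated)
        outside = self.annotated_raw - self.background
        if outside:
            warnings.warn(
                f"{len(outside)} annotated gene(s) absent from the background; "
                "kept but excluded from enrichment",
                stacklevel=2,
            )
        self.annotated = self.annotated_raw & self.background

    @property
    def prevalence(self) -> float:
        """Fraction of background genes in the set."""
        if not self.background:
            return float("nan")
        return len(self.annotated) / len(self.background)

    def is_annotated(self, gene: str) -> bool:
        return gene in self.annotated

    def require_universe(self, genes: Iterable[str]) -> None:
        """Raise if any gene lies outside the background universe."""
        stray = set(genes) - self.background
        if stray:
            raise ConsistencyError(
                f"{len(stray)} gene(s) outside the annotation background, "
                f"e.g. {sorted(stray)[:3]}"
            )
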