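"""Readers and writers for every on-disk format the pipeline touches.

Colony-size tables use the dialect of the *gitter* colony-quantitation
output: a whitespace/tab-delimited table with one record per grid position
and at least ``row``, ``col`` and ``size`` columns (1-based coordinates,
row 1 top-left); lines starting ``#`` are comments.  A size of 0 encodes an
absent colony.  Layouts, annotations, phenotype tables and hit lists are
plain TSV with a ``#``-prefixed provenance header.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .errors import (
    BoundsError,
    DuplicatePositionError,
    ParseError,
)
from .types import (
    EMPTY_TOKEN,
    DatasetKey,
    GeneSetAnnotation,
    LibraryLayout,
    PlateGrid,
)

_NUMERIC_HINT = set("0123456789+-.eE")


def provenance_header(**meta: object) -> list[str]:
    """Standard provenance comment lines (tool version + key=value pairs)."""
    lines = [f"# respscreen {__version__}"]
    for k in sorted(meta):
        lines.append(f"# {k}={meta[k]}")
    return lines


def config_hash(obj: object) -> str:
    """Short stable hash of a configuration representation."""
    return hashlib.sha256(repr(obj).encode()).hexdigest()[:12]


# ---------------------------------------------------------------- colony .dat


def write_colony_table(path: str | Path, grid: PlateGrid, **meta: object) -> None:
    """Write a plate grid in the gitter-style .dat dialect.

    One line per grid position (row-major); missing positions are written
    with size 0 and flag ``A`` (absent).
    """
    path = Path(path)
    rows, cols = grid.shape
    with path.open("w") as fh:
        for line in provenance_header(**meta):
            fh.write(line + "\n")
        fh.write("row\tcol\tsize\tflags\n")
        for i in range(rows):
            for j in range(cols):
                absent = grid.missing[i, j]
                size = 0.0 if absent else grid.sizes[i, j]
                flag = "A" if absent else "-"
                fh.write(f"{i + 1}\t{j + 1}\t{size:.6g}\t{flag}\n")


def read_colony_table(path: str | Path, grid_rows: int, grid_cols: int) -> PlateGrid:
    """Read a gitter-style colony-size table into a raw :class:`PlateGrid`.

    Accepts any whitespace/tab table with ``row``/``col``/``size`` columns by
    name (headerless files are assumed to carry them as the first three
    columns).  Positions absent from the file or with size 0 get the
    missing-mask set; duplicate positions and out-of-range coordinates are
    errors naming the offending line.
    """
    path = Path(path)
    sizes = np.zeros((grid_rows, grid_cols))
    missing = np.ones((grid_rows, grid_cols), dtype=bool)
    seen: set[tuple[int, int]] = set()
    col_idx = {"row": 0, "col": 1, "size": 2}
    header_parsed = False

    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if not header_parsed:
                header_parsed = True
                lowered = [f.lower() for f in fields]
                if {"row", "col", "size"}.issubset(lowered):
                    col_idx = {name: lowered.index(name) for name in ("row", "col", "size")}
                    continue  # header line consumed
                # headerless: fall through and parse this line as data
            try:
                r = int(fields[col_idx["row"]])
                c = int(fields[col_idx["col"]])
                size = float(fields[col_idx["size"]])
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path.name}:{lineno}: malformed record: {line!r}") from exc
            if not (1 <= r <= grid_rows and 1 <= c <= grid_cols):
                raise BoundsError(
                    f"{path.name}:{lineno}: position ({r}, {c}) outside "
                    f"{grid_rows}x{grid_cols} grid"
                )
            if (r, c) in seen:
                raise DuplicatePositionError(
                    f"{path.name}:{lineno}: duplicate position ({r}, {c})"
                )
            seen.add((r, c))
            if size < 0:
                raise ParseError(f"{path.name}:{lineno}: negative size {size}")
            sizes[r - 1, c - 1] = size
            missing[r - 1, c - 1] = size == 0.0
    return PlateGrid(sizes, missing, stage="raw")


# ------------------------------------------------------------------ TSV core


def write_table(path: str | Path, table: pd.DataFrame, **meta: object) -> None:
    """Write a DataFrame as TSV with a provenance comment header."""
    path = Path(path)
    with path.open("w") as fh:
        for line in provenance_header(**meta):
            fh.write(line + "\n")
        table.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# ------------------------------------------------------- layout / annotation


def write_layout(path: str | Path, layout: LibraryLayout, **meta: object) -> None:
    write_table(
        path,
        layout.table,
        grid_rows=layout.grid_rows,
        grid_cols=layout.grid_cols,
        **meta,
    )


def read_layout(path: str | Path) -> LibraryLayout:
    """Read a layout TSV; grid dimensions come from the provenance header or data."""
    path = Path(path)
    grid_rows = grid_cols = None
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            stripped = line[1:].strip()
            if stripped.startswith("grid_rows="):
                grid_rows = int(stripped.split("=", 1)[1])
            elif stripped.startswith("grid_cols="):
                grid_cols = int(stripped.split("=", 1)[1])
    table = read_table(path)
    if grid_rows is None:
        grid_rows = int(table["row"].max())
    if grid_cols is None:
        grid_cols = int(table["col"].max())
    return LibraryLayout(table, grid_rows, grid_cols)


def write_annotation(
    path: str | Path, annotation: GeneSetAnnotation, **meta: object
) -> None:
    """Write one row per annotated gene: (gene, set_name)."""
    table = pd.DataFrame(
        {"gene": sorted(annotation.annotated_raw),
         "set_name": annotation.set_name}
    )
    write_table(path, table, set_name=annotation.set_name, **meta)


def read_annotation(
    path: str | Path,
    background: Iterable[str] | None = None,
    set_name: str | None = None,
) -> GeneSetAnnotation:
    """Read an annotation TSV (columns gene, set_name).

    ``background`` is the gene universe (typically the layout's genes); when
    omitted the listed genes themselves serve as background, which is only
    adequate for round-trip checks.
    """
    table = read_table(path)
    if "gene" not in table.columns:
        raise ParseError(f"{Path(path).name}: annotation table needs a 'gene' column")
    genes = table["gene"].astype(str).tolist()
    if set_name is None:
        set_name = (
            str(table["set_name"].iloc[0]) if "set_name" in table.columns and len(table)
            else "gene_set"
        )
    if background is None:
        background = genes
    return GeneSetAnnotation(set_name, genes, background)


# ------------------------------------------------------------- ground truth


def write_ground_truth(path: str | Path, truth, **meta: object) -> None:
    write_table(path, truth.table, **meta)


def read_ground_truth(path: str | Path):
    from .synthetic_screen import GroundTruth

    return GroundTruth(read_table(path))


# -------------------------------------------------------------- screen trees


def plate_filename(key: DatasetKey) -> str:
    return f"{key.label}.dat"


def write_screen(
    outdir: str | Path, grids: Mapping[DatasetKey, PlateGrid], **meta: object
) -> list[Path]:
    """Write every plate of a screen as one .dat file per (dataset, plate)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for key in sorted(grids, key=lambda k: k.label):
        p = outdir / plate_filename(key)
        write_colony_table(p, grids[key], dataset=key.label, **meta)
        written.append(p)
    return written


def read_screen(
    indir: str | Path, grid_rows: int, grid_cols: int
) -> dict[DatasetKey, PlateGrid]:
    """Read every ``*.dat`` plate file in a directory, parsing keys from names."""
    indir = Path(indir)
    grids: dict[DatasetKey, PlateGrid] = {}
    for p in sorted(indir.glob("*.dat")):
        key = parse_plate_filename(p.name)
        grid = read_colony_table(p, grid_rows, grid_cols)
        grid.key = key
        grids[key] = grid
    return grids


def parse_plate_filename(name: str) -> DatasetKey:
    """Parse ``<background>_<medium>_b<B>_t<T>_p<plate>.dat`` into a key."""
    stem = name.removesuffix(".dat")
    parts = stem.split("_")
    if len(parts) != 5:
        raise ParseError(f"unrecognized plate filename {name!r}")
    bg, medium, b, t, p = parts
    try:
        return DatasetKey(
            bg, medium, int(b.removeprefix("b")), int(t.removeprefix("t")),
            plate_id=p.removeprefix("p"),
        )
    except ValueError as exc:
        raise ParseError(f"unrecognized plate filename {name!r}") from exc
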