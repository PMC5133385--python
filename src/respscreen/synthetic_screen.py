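"""Synthetic colony-array screens with the statistical structure of a real one.

Emulates a respiratory-growth screen of a fission-yeast deletion library:
3420 strains arrayed at 384 colonies per plate over 9 plates, grown in 2
genetic backgrounds (auxotroph, prototroph) on 2 media (glucose, glycerol)
with 2 biological x 2 technical repeats — 16 datasets in total.  Colony
sizes are generated multiplicatively:

    size(g, p, i, j, c, b, t) = base * P(p) * E(i, j) * B(p, i, j)
                                      * S(g) * J(g, b) * M(g, c, b) * eps

where ``P`` is a per-plate lognormal scale (plate-to-plate scan and agar
differences), ``E`` a deterministic edge-effect profile inflating border
rows/columns, ``B`` a smooth sum of Gaussian bumps (local agar/humidity
artefacts), ``S`` a per-gene baseline fitness effect shared by all datasets,
``J`` a per-gene between-biological-repeat jitter, ``M`` the
respiratory-deficiency multiplier (1 on glucose; < 1 on glycerol for
deficient strains, jittered per biological repeat), and ``eps`` lognormal
within-technical-repeat noise.  ``S`` and ``J`` cancel exactly in the
glycerol/glucose colony-size ratio, so the ratio phenotype of a strain is
its (jittered) deficiency multiplier plus technical noise.

Respiratory-deficient strains are concentrated in a 'mitochondrion'-style
annotation with ~13% background prevalence, so that hit lists recovered by
the analysis are enriched for the annotation, as in the real screen.

All randomness derives from one integer seed; named substreams make every
component reproducible independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConsistencyError, InvalidParameterError
from .types import (
    EMPTY_TOKEN,
    DatasetKey,
    GeneSetAnnotation,
    LibraryLayout,
    PlateGrid,
    enumerate_dataset_keys,
)

# substream tags (stable; reordering would change generated screens)
_S_LAYOUT = 1
_S_ANNOT = 2
_S_DEFICIENT = 3
_S_MULT = 4
_S_STRAIN = 5
_S_BIOJITTER = 6
_S_PLATE = 7


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the synthetic screen generator.

    Defaults reproduce the real screen's design (library size, plate format,
    repeat structure, annotation prevalence) and plausible noise magnitudes
    for colony-array data; ``bio_noise_cv > tech_noise_cv`` encodes the
    observation that technical repeats agree more closely than biological
    repeats.
    """

    n_genes: int = 3420
    grid_rows: int = 16
    grid_cols: int = 24
    n_bio: int = 2
    n_tech: int = 2
    base_size: float = 1000.0
    plate_effect_cv: float = 0.15
    edge_effect_strength: float = 0.3
    edge_depth: int = 1
    spatial_blob_count: int = 2
    spatial_blob_amplitude: float = 0.3
    spatial_blob_sigma: float = 3.0
    missing_prob: float = 0.02
    tech_noise_cv: float = 0.08
    bio_noise_cv: float = 0.18
    strain_effect_cv: float = 0.15
    frac_annotated: float = 0.13
    frac_deficient_given_annotated: float = 0.35
    frac_deficient_given_unannotated: float = 0.02
    deficiency_effect_range: tuple[float, float] = (0.3, 0.8)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise InvalidParameterError("n_genes must be >= 1")
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise InvalidParameterError("grid dimensions must be positive")
        for name in ("missing_prob", "frac_annotated",
                     "frac_deficient_given_annotated",
                     "frac_deficient_given_unannotated"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidParameterError(f"{name} must be in [0, 1], got {v}")
        for name in ("plate_effect_cv", "edge_effect_strength",
                     "spatial_blob_amplitude", "tech_noise_cv",
                     "bio_noise_cv", "strain_effect_cv"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be nonnegative")
        lo, hi = self.deficiency_effect_range
        if not (0.0 < lo <= hi < 1.0):
            raise InvalidParameterError(
                "deficiency_effect_range must lie strictly inside (0, 1)"
            )
        if self.bio_noise_cv < self.tech_noise_cv:
            raise InvalidParameterError(
                "bio_noise_cv must be >= tech_noise_cv (biological repeats "
                "vary more than technical repeats)"
            )

    @property
    def n_plates(self) -> int:
        return math.ceil(self.n_genes / (self.grid_rows * self.grid_cols))


@dataclass
class GroundTruth:
    """Per-gene truth labels of a simulated screen.

    ``table`` columns: gene, annotated, deficient, base_multiplier, and one
    ``multiplier_b{b}`` column per biological repeat (the jittered glycerol
    multiplier actually applied; exactly 1 for non-deficient genes).
    """

    table: pd.DataFrame

    @property
    def deficient_genes(self) -> set[str]:
        return set(self.table.loc[self.table["deficient"], "gene"])

    @property
    def annotated_genes(self) -> set[str]:
        return set(self.table.loc[self.table["annotated"], "gene"])

    def multiplier(self, bio_repeat: int) -> pd.Series:
        return self.table.set_index("gene")[f"multiplier_b{bio_repeat}"]


def _rng(seed: int, *ids: int) -> np.random.Generator:
    """Deterministic named substream of the global seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, ids)]))


def _lognormal_unit_mean(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Lognormal draws with mean 1 and coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(size if size is not None else ())
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def generate_layout(
    n_genes: int, grid_rows: int = 16, grid_cols: int = 24, seed: int = 0
) -> LibraryLayout:
    """Array ``n_genes`` strains onto as many plates as needed.

    Genes are assigned to positions in a seed-determined random order,
    filling plates sequentially row-major; leftover positions on the last
    plate are empty.
    """
    if n_genes < 1:
        raise InvalidParameterError("n_genes must be >= 1")
    if grid_rows < 1 or grid_cols < 1:
        raise InvalidParameterError("grid dimensions must be positive")
    per_plate = grid_rows * grid_cols
    n_plates = math.ceil(n_genes / per_plate)
    genes = [f"SPS{i:04d}" for i in range(1, n_genes + 1)]
    order = _rng(seed, _S_LAYOUT).permutation(n_genes)

    records = []
    for slot in range(n_plates * per_plate):
        plate = slot // per_plate + 1
        r = (slot % per_plate) // grid_cols + 1
        c = (slot % per_plate) % grid_cols + 1
        gene = genes[order[slot]] if slot < n_genes else EMPTY_TOKEN
        records.append((plate, r, c, gene))
    table = pd.DataFrame(records, columns=["plate", "row", "col", "gene"])
    return LibraryLayout(table, grid_rows, grid_cols)


def generate_annotation(
    layout: LibraryLayout,
    frac_annotated: float = 0.13,
    seed: int = 0,
    set_name: str = "mitochondrion",
) -> GeneSetAnnotation:
    """Annotate each layout gene independently with probability ``frac_annotated``."""
    if not 0.0 <= frac_annotated <= 1.0:
        raise InvalidParameterError("frac_annotated must be in [0, 1]")
    genes = layout.genes
    draws = _rng(seed, _S_ANNOT).random(len(genes)) < frac_annotated
    annotated = [g for g, a in zip(genes, draws) if a]
    return GeneSetAnnotation(set_name, annotated, genes)


def _edge_profile(params: SimulationParams) -> np.ndarray:
    """Deterministic border inflation, separable as row x column factors.

    Border rows and border columns (outermost ``edge_depth``) are inflated
    by ``1 + edge_effect_strength``; corners receive both factors.  The
    separable form matches the row/column-specific artefact that the
    row-then-column median correction removes exactly.
    """
    r = np.ones(params.grid_rows)
    c = np.ones(params.grid_cols)
    d = params.edge_depth
    if d > 0 and params.edge_effect_strength > 0:
        r[:d] = r[-d:] = 1.0 + params.edge_effect_strength
        c[:d] = c[-d:] = 1.0 + params.edge_effect_strength
    return np.outer(r, c)


def _blob_profile(rng: np.random.Generator, params: SimulationParams) -> np.ndarray:
    """Smooth multiplicative artefact: 1 + sum of Gaussian bumps."""
    b = np.ones((params.grid_rows, params.grid_cols))
    if params.spatial_blob_count == 0 or params.spatial_blob_amplitude == 0:
        return b
    ii, jj = np.meshgrid(
        np.arange(params.grid_rows), np.arange(params.grid_cols), indexing="ij"
    )
    for _ in range(params.spatial_blob_count):
        ci = rng.uniform(0, params.grid_rows - 1)
        cj = rng.uniform(0, params.grid_cols - 1)
        amp = rng.uniform(0, params.spatial_blob_amplitude)
        d2 = (ii - ci) ** 2 + (jj - cj) ** 2
        b += amp * np.exp(-d2 / (2.0 * params.spatial_blob_sigma**2))
    return b


def simulate_screen(
    layout: LibraryLayout,
    annotation: GeneSetAnnotation,
    params: SimulationParams,
) -> tuple[dict[DatasetKey, PlateGrid], GroundTruth]:
    """Generate raw plate grids for all datasets of a screen, plus truth labels.

    Returns a dict keyed by :class:`DatasetKey` (with ``plate_id`` set) with
    one :class:`PlateGrid` per dataset x plate, and the :class:`GroundTruth`
    recording which genes are deficient and the multipliers applied.
    """
    genes = layout.genes
    if set(genes) != set(annotation.background):
        raise ConsistencyError("layout and annotation gene universes differ")
    n = len(genes)
    seed = params.seed

    annotated = np.array([annotation.is_annotated(g) for g in genes])
    p_def = np.where(
        annotated,
        params.frac_deficient_given_annotated,
        params.frac_deficient_given_unannotated,
    )
    deficient = _rng(seed, _S_DEFICIENT).random(n) < p_def

    lo, hi = params.deficiency_effect_range
    base_mult = np.where(deficient, _rng(seed, _S_MULT).uniform(lo, hi, n), 1.0)

    strain = _lognormal_unit_mean(_rng(seed, _S_STRAIN), params.strain_effect_cv, n)

    # per-(gene, background, bio repeat) jitter of strain effects, and the
    # per-bio-repeat realisation of the deficiency multiplier
    jitter: dict[tuple[str, int], np.ndarray] = {}
    for bi, bg in enumerate(("auxotroph", "prototroph")):
        for b in range(1, params.n_bio + 1):
            rng = _rng(seed, _S_BIOJITTER, bi, b)
            jitter[(bg, b)] = _lognormal_unit_mean(rng, params.bio_noise_cv, n)
    mult_by_rep: dict[int, np.ndarray] = {}
    for b in range(1, params.n_bio + 1):
        rng = _rng(seed, _S_BIOJITTER, 99, b)
        jit = _lognormal_unit_mean(rng, params.bio_noise_cv, n)
        mult_by_rep[b] = np.where(deficient, np.minimum(base_mult * jit, 1.0), 1.0)

    edge = _edge_profile(params)
    gene_index = {g: i for i, g in enumerate(genes)}

    grids: dict[DatasetKey, PlateGrid] = {}
    keys = enumerate_dataset_keys(params.n_bio, params.n_tech)
    for di, key in enumerate(keys):
        for plate in layout.plate_ids:
            rng = _rng(seed, _S_PLATE, di, plate)
            plate_scale = _lognormal_unit_mean(rng, params.plate_effect_cv, None)
            blobs = _blob_profile(rng, params)
            eps = _lognormal_unit_mean(
                rng, params.tech_noise_cv, (params.grid_rows, params.grid_cols)
            )
            miss_draw = rng.random((params.grid_rows, params.grid_cols))

            gene_grid = layout.gene_grid(plate)
            empty = layout.empty_mask(plate)
            gmul = np.ones((params.grid_rows, params.grid_cols))
            for (r, c), g in np.ndenumerate(gene_grid):
                if g is None:
                    continue
                gi = gene_index[g]
                f = strain[gi] * jitter[(key.background, key.bio_repeat)][gi]
                if key.medium == "glycerol":
                    f *= mult_by_rep[key.bio_repeat][gi]
                gmul[r, c] = f

            sizes = params.base_size * plate_scale * edge * blobs * gmul * eps
            missing = empty | (miss_draw < params.missing_prob)
            sizes[missing] = 0.0
            grids[key.with_plate(str(plate))] = PlateGrid(
                sizes, missing, key=key.with_plate(str(plate)), stage="raw"
            )

    truth_cols = {
        "gene": genes,
        "annotated": annotated,
        "deficient": deficient,
        "base_multiplier": base_mult,
    }
    for b in range(1, params.n_bio + 1):
        truth_cols[f"multiplier_b{b}"] = mult_by_rep[b]
    truth = GroundTruth(pd.DataFrame(truth_cols))
    return grids, truth


def simulate_default_screen(
    seed: int = 0, params: SimulationParams | None = None
) -> tuple[LibraryLayout, GeneSetAnnotation, dict[DatasetKey, PlateGrid], GroundTruth]:
    """Convenience wrapper: layout + annotation + full screen with one seed."""
    if params is None:
        params = SimulationParams(seed=seed)
    else:
        params = SimulationParams(**{**params.__dict__, "seed": seed})
    layout = generate_layout(
        params.n_genes, params.grid_rows, params.grid_cols, seed=params.seed
    )
    annotation = generate_annotation(
        layout, params.frac_annotated, seed=params.seed
    )
    grids, truth = simulate_screen(layout, annotation, params)
    return layout, annotation, grids, truth
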