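import numpy as np
import pytest

import respscreen as rs
from respscreen.pipeline import RunConfig, run_pipeline
from respscreen.synthetic_screen import SimulationParams
from respscreen.types import PlateGrid


def make_grid(sizes, missing=None, stage="raw", **kw):
    sizes = np.asarray(sizes, dtype=float)
    if missing is None:
        missing = np.zeros_like(sizes, dtype=bool)
    return PlateGrid(sizes, missing, stage=stage, **kw)


@pytest.fixture
def uniform_grid():
    return make_grid(np.full((16, 24), 7.0))


def noise_free_params(**overrides) -> SimulationParams:
    """Generator settings with every stochastic component switched off."""
    base = dict(
        n_genes=192,
        grid_rows=8,
        grid_cols=12,
        plate_effect_cv=0.0,
        edge_effect_strength=0.0,
        spatial_blob_count=0,
        spatial_blob_amplitude=0.0,
        missing_prob=0.0,
        tech_noise_cv=0.0,
        bio_noise_cv=0.0,
        strain_effect_cv=0.0,
        frac_deficient_given_annotated=0.0,
        frac_deficient_given_unannotated=0.0,
        seed=11,
    )
    base.update(overrides)
    return SimulationParams(**base)


@pytest.fixture
def small_screen():
    """A small noisy screen (192 genes, 2 plates) with defaults-like noise."""
    params = SimulationParams(n_genes=192, grid_rows=8, grid_cols=12, seed=7)
    layout, annotation, grids, truth = rs.simulate_default_screen(
        seed=7, params=params
    )
    return params, layout, annotation, grids, truth


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """Full pipeline on the default synthetic screen (3420 genes, seed 1)."""
    outdir = tmp_path_factory.mktemp("default_run")
    return run_pipeline(RunConfig(seed=1), outdir)
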