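"""One-command orchestration: simulate -> normalize -> phenotype -> qc -> hits.

A :class:`RunConfig` gathers every tunable parameter of every stage with
defaults equal to the analysis' standard values (SE cutoff 0.4, minimum
glucose size 0.12, enrichment floor 40%, top-100 lists, threshold grid step
0.01).  Unknown configuration keys are rejected before any stage runs, and
the same config + seed always produces a byte-identical output tree (no
timestamps are written).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, enrichment, hitcalling, normalization, phenotype, qc_stats
from .errors import ConfigError
from .plate_io import (
    config_hash,
    read_annotation,
    read_layout,
    read_screen,
    write_annotation,
    write_ground_truth,
    write_layout,
    write_screen,
    write_table,
)
from .synthetic_screen import SimulationParams, simulate_default_screen
from .types import BACKGROUNDS, DatasetKey, PlateGrid


@dataclass
class NormalizationConfig:
    window: int = 3
    min_count: int = 3
    polish_iterations: int = 1


@dataclass
class PhenotypeConfig:
    se_max: float = 0.4
    min_glucose: float = 0.12


@dataclass
class HitcallingConfig:
    min_enrichment: float = 40.0
    min_overlap: int = 10
    top_n: int = 100
    grid_start: float = 0.05
    grid_stop: float = 1.20
    grid_step: float = 0.01

    @property
    def grid(self) -> np.ndarray:
        return np.round(
            np.arange(self.grid_start, self.grid_stop + 1e-9, self.grid_step), 10
        )


@dataclass
class RunConfig:
    """Full pipeline configuration (YAML-loadable; unknown keys rejected)."""

    seed: int = 0
    input_dir: str | None = None  # read raw screen from here instead of simulating
    simulation: SimulationParams = field(default_factory=SimulationParams)
    normalization: NormalizationConfig = field(default_factory=NormalizationConfig)
    phenotype: PhenotypeConfig = field(default_factory=PhenotypeConfig)
    hitcalling: HitcallingConfig = field(default_factory=HitcallingConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data or {})
        kwargs: dict = {}
        sections = {
            "simulation": SimulationParams,
            "normalization": NormalizationConfig,
            "phenotype": PhenotypeConfig,
            "hitcalling": HitcallingConfig,
        }
        valid_top = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - valid_top
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        for name, typ in sections.items():
            sub = data.pop(name, {})
            if not isinstance(sub, dict):
                raise ConfigError(f"config section {name!r} must be a mapping")
            valid = {f.name for f in dataclasses.fields(typ)}
            bad = set(sub) - valid
            if bad:
                raise ConfigError(f"unknown key(s) in {name!r}: {sorted(bad)}")
            kwargs[name] = typ(**sub)
        kwargs.update(data)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open() as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def hash(self) -> str:
        return config_hash(self.to_dict())


def normalize_screen(
    grids: dict[DatasetKey, PlateGrid], layout, cfg: NormalizationConfig
) -> dict[DatasetKey, PlateGrid]:
    out = {}
    empty_masks = {p: layout.empty_mask(p) for p in layout.plate_ids}
    for key, grid in grids.items():
        out[key] = normalization.normalize_plate(
            grid,
            layout_empty=empty_masks[int(key.plate_id)],
            window=cfg.window,
            min_count=cfg.min_count,
            polish_iterations=cfg.polish_iterations,
        )
    return out


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run every stage, writing a deterministic output tree under ``outdir``.

    Returns a result dict with the key in-memory products (tables, selected
    thresholds, hit lists) for programmatic use.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"seed": config.seed, "config_hash": config.hash}
    log_lines: list[str] = [f"respscreen {__version__} run (seed={config.seed}, "
                            f"config={config.hash})"]

    # ---- stage: inputs (simulate or read) ----------------------------------
    if config.input_dir is None:
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        layout, annotation, raw, truth = simulate_default_screen(
            seed=config.seed, params=sim
        )
        simdir = outdir / "simulated"
        simdir.mkdir(exist_ok=True)
        write_layout(simdir / "layout.tsv", layout, **meta)
        write_annotation(simdir / "annotation.tsv", annotation, **meta)
        write_ground_truth(simdir / "ground_truth.tsv", truth, **meta)
        write_screen(simdir / "raw_plates", raw, **meta)
        log_lines.append(
            f"[simulate] {layout.n_genes} genes on {layout.n_plates} plates; "
            f"{len(raw)} plate grids; {len(truth.deficient_genes)} deficient strains"
        )
    else:
        indir = Path(config.input_dir)
        layout = read_layout(indir / "layout.tsv")
        annotation = read_annotation(
            indir / "annotation.tsv", background=layout.genes
        )
        raw = read_screen(indir / "raw_plates", layout.grid_rows, layout.grid_cols)
        truth = None
        log_lines.append(
            f"[read] {layout.n_genes} genes; {len(raw)} plate grids from {indir}"
        )

    # ---- stage: normalization ----------------------------------------------
    norm = normalize_screen(raw, layout, config.normalization)
    write_screen(outdir / "normalized_plates", norm, **meta)
    log_lines.append(f"[normalize] {len(norm)} plates normalized "
                     f"(window={config.normalization.window})")

    # ---- stage: phenotype ---------------------------------------------------
    long_df = phenotype.screen_long_table(norm, layout)
    summary = phenotype.summarize_technical_table(long_df)
    summary = phenotype.apply_qc_filters(
        summary,
        se_max=config.phenotype.se_max,
        min_glucose=config.phenotype.min_glucose,
    )
    ratios = phenotype.compute_ratios(summary)
    write_table(outdir / "phenotypes_summary.tsv", summary, **meta)
    write_table(outdir / "ratios.tsv", ratios, **meta)
    flags = phenotype.qc_flag_counts(summary)
    log_lines.append(
        f"[phenotype] {len(summary)} summaries, {int(ratios['ratio'].notna().sum())} "
        f"ratios; flags {flags}"
    )

    # ---- stage: qc ----------------------------------------------------------
    qcdir = outdir / "qc"
    qcdir.mkdir(exist_ok=True)
    matrix = qc_stats.dataset_matrix(long_df)
    corr = qc_stats.correlation_matrix(matrix)
    write_table(qcdir / "correlations.tsv", corr.reset_index(names="dataset"), **meta)
    clusters = qc_stats.cluster_datasets(matrix)
    (qcdir / "dendrogram.newick").write_text(clusters.to_newick() + "\n")
    concord = qc_stats.replicate_concordance(corr)
    write_table(qcdir / "replicate_concordance.tsv", pd.DataFrame([concord]), **meta)
    log_lines.append(f"[qc] concordance {concord}")

    # ---- stage: hits --------------------------------------------------------
    hitdir = outdir / "hits"
    hitdir.mkdir(exist_ok=True)
    per_bg: dict[str, dict] = {}
    named_lists: dict[str, list[str]] = {}
    for bg in BACKGROUNDS:
        r1 = phenotype.ratios_for(ratios, bg, 1)
        r2 = phenotype.ratios_for(ratios, bg, 2)
        curve = hitcalling.threshold_curve(r1, r2, annotation,
                                           grid=config.hitcalling.grid)
        thr = hitcalling.select_threshold(
            curve,
            min_enrichment=config.hitcalling.min_enrichment,
            min_overlap=config.hitcalling.min_overlap,
        )
        hits = hitcalling.overlap_hits(r1, r2, thr) if thr is not None else []
        write_table(hitdir / f"curve_{bg}.tsv", curve.table, **meta)
        write_table(hitdir / f"hits_{bg}.tsv", pd.DataFrame({"gene": hits}), **meta)
        top = {
            b: enrichment.top_n_hits(phenotype.ratios_for(ratios, bg, b),
                                     n=config.hitcalling.top_n)
            for b in (1, 2)
        }
        per_bg[bg] = {"curve": curve, "threshold": thr, "hits": hits, "top": top}
        named_lists[bg] = hits
        log_lines.append(
            f"[hits] {bg}: threshold={thr}, overlap={len(hits)} genes"
        )

    merged = hitcalling.merge_backgrounds(*(named_lists[bg] for bg in BACKGROUNDS))
    named_lists["merged"] = merged
    enr = enrichment.enrichment_table(
        {k: v for k, v in named_lists.items() if v}, annotation
    )
    write_table(hitdir / "hits_merged.tsv", pd.DataFrame({"gene": merged}), **meta)
    write_table(hitdir / "enrichment.tsv", enr, **meta)
    log_lines.append(f"[hits] merged: {len(merged)} genes")

    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")

    return {
        "layout": layout,
        "annotation": annotation,
        "truth": truth,
        "normalized": norm,
        "summary": summary,
        "ratios": ratios,
        "correlations": corr,
        "clusters": clusters,
        "concordance": concord,
        "per_background": per_bg,
        "merged_hits": merged,
        "enrichment": enr,
    }
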