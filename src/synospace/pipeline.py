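"""End-to-end orchestration: per-sample processing, cohort longitudinal
metrics and a self-contained demo cohort.

These are thin compositions of the stage functions; every stochastic step
takes its seed from the :class:`PipelineConfig` so a rerun with the same
configs is bit-identical.
"""

from __future__ import annotations

import warnings

import anndata as ad
import pandas as pd

from . import gating, kde, preprocess
from .io import PipelineConfig
from .simulate import Cohort, SimConfig, generate_cohort

__all__ = [
    "process_sample",
    "sample_longitudinal_metrics",
    "cohort_longitudinal",
    "run_demo",
]


def process_sample(cells: ad.AnnData, cfg: PipelineConfig) -> ad.AnnData:
    """QC -> normalize -> type -> subtype -> niches for one (or more) samples."""
    out = preprocess.qc_filter(cells, min_features=cfg.qc_min_features)
    preprocess.normalize(out)
    preprocess.assign_cell_types(out, min_score=cfg.type_min_score)
    preprocess.classify_fibroblast_subtypes(out, lowrna_threshold=cfg.lowrna_features)
    preprocess.segment_niches(out, patch_size=cfg.niche_patch_size,
                              resolution=cfg.niche_resolution,
                              knn=cfg.niche_knn, seed=cfg.seed)
    return out


def sample_longitudinal_metrics(cells: ad.AnnData, transcripts: pd.DataFrame,
                                cfg: PipelineConfig,
                                gene: str = "COMP") -> dict:
    """Per-sample %COMP+ fibroblasts and COMP-high-region cell density."""
    comp_pos = gating.comp_positive_fraction(cells, "fibroblast", gene)
    pts = transcripts[transcripts["gene"] == gene]
    density = float("nan")
    if len(pts) >= 10:
        field = kde.compute_kde(pts, pixel_size=cfg.kde_pixel_size,
                                bandwidth=cfg.kde_bandwidth or 30.0)
        mask = kde.hdr_mask(field, mass=cfg.hdr_mass)
        density = kde.region_cell_density(mask, cells)
    return {"comp_positive": comp_pos, "comphi_density": density}


def cohort_longitudinal(cohort: Cohort, cfg: PipelineConfig,
                        gene: str = "COMP") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Longitudinal records and immune-abundance changes for a cohort.

    Returns ``(records, immune)``: one row per patient with pre/post %COMP+
    fibroblasts, the delta and stability flag, and COMP-high-region cell
    densities; and the tidy per-(patient, immune type) proportion table.
    """
    processed: dict[str, ad.AnnData] = {}
    metrics = {}
    for sid, sample in cohort.samples.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cells = process_sample(sample.cells, cfg) if cfg.niche_patch_size else sample.cells
        processed[sid] = cells
        metrics[sid] = sample_longitudinal_metrics(cells, sample.transcripts, cfg, gene)
    per_sample = pd.DataFrame(metrics).T
    records = gating.longitudinal_table(per_sample, cohort.meta,
                                        stability_threshold=cfg.delta_stability)
    immune = gating.immune_abundance_change(processed, cohort.meta)
    return records, immune


def run_demo(seed: int = 0, n_patients: int = 4) -> dict:
    """Small end-to-end run on a simulated cohort; returns all stage outputs.

    Used by the command line ``demo`` stage and by the determinism checks.
    """
    pipe_cfg = PipelineConfig(qc_min_features=5, seed=seed)
    sim_cfg = SimConfig(
        width=1200.0, height=1200.0, n_vessels=6, fibro_density=800.0,
        n_aggregates=2, aggregate_radius=150.0, aggregate_cells=150,
        lining_depth=120.0, adipose_size=400.0,
        n_patients=n_patients, transcript_genes=("COMP", "POSTN", "COL1A1"),
        seed=seed,
    )
    cohort = generate_cohort(sim_cfg)
    records, immune = cohort_longitudinal(cohort, pipe_cfg)
    first = cohort.meta["sample_id"].iloc[0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cells = process_sample(cohort.samples[first].cells, pipe_cfg)
        summary = preprocess.niche_summary(cells, per_cell_area=pipe_cfg.per_cell_area)
    return {
        "cohort_meta": cohort.meta,
        "records": records,
        "immune": immune,
        "first_sample_cells": cells,
        "niche_areas": summary.area_fractions,
        "provenance": pipe_cfg.provenance(),
    }
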