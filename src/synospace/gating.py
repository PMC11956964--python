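"""Mutually exclusive high-expresser gating (COMP-high vs POSTN-high) and
paired pre/post longitudinal metrics.

Gating follows the flow-cytometry-like convention used on spatial counts:
among cells *expressing* a gene (raw count > 0), the top-q quantile defines
candidate high cells; an exclusivity cap on the partner gene (e.g.
``POSTN <= 3.5`` counts for COMP-high) removes double-positives, and any cell
still qualifying for both gates is dropped from both. Gating operates on raw
counts by default (the caps are printed on a counts scale); a switch to
normalized values is provided.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

from ._stats import mannwhitney_u, pearson_r
from .io import ValidationError, gene_vector

log = logging.getLogger(__name__)

__all__ = [
    "GateResult",
    "gate_biexpression",
    "compare_gated_expression",
    "comp_positive_fraction",
    "paired_delta",
    "longitudinal_table",
    "delta_density_correlation",
    "immune_abundance_change",
]

IMMUNE_TYPES = ("T", "B", "plasma", "myeloid")


@dataclass
class GateResult:
    """Per-cell gate labels plus the thresholds that produced them."""

    labels: pd.Series            # 'geneA-hi' | 'geneB-hi' | 'ungated'
    gene_a: str
    gene_b: str
    q: float
    thresholds: dict = field(default_factory=dict)
    n_overlap_dropped: int = 0

    def ids(self, which: str) -> pd.Index:
        return self.labels.index[self.labels == which]


def gate_biexpression(cells: ad.AnnData, gene_a: str = "COMP",
                      gene_b: str = "POSTN", q: float = 0.25,
                      cap_a: float | None = None,
                      cap_b: float | None = None,
                      population: np.ndarray | str | None = "fibroblast",
                      layer: str | None = None) -> GateResult:
    """Mutually exclusive top-quantile gates on two genes.

    ``cap_b`` caps the partner gene for the A gate (A-high additionally needs
    ``gene_b <= cap_b``) and symmetrically for ``cap_a``. Residual overlap is
    resolved by dropping the cell from both gates (logged).
    """
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    for cap in (cap_a, cap_b):
        if cap is not None and cap < 0:
            raise ValueError("exclusivity caps must be non-negative")
    if isinstance(population, str):
        pop = (cells.obs["cell_type"].astype(str) == population).to_numpy()
    elif population is None:
        pop = np.ones(cells.n_obs, dtype=bool)
    else:
        pop = np.asarray(population, dtype=bool)
    va = gene_vector(cells, gene_a, layer=layer)
    vb = gene_vector(cells, gene_b, layer=layer)
    thresholds = {}
    candidates = {}
    for gene, v in ((gene_a, va), (gene_b, vb)):
        expressing = pop & (v > 0)
        if not expressing.any():
            raise ValidationError(f"no cells express {gene}")
        thr = float(np.quantile(v[expressing], 1.0 - q))
        thresholds[gene] = thr
        candidates[gene] = expressing & (v >= thr)
    a_hi = candidates[gene_a].copy()
    b_hi = candidates[gene_b].copy()
    if cap_b is not None:
        a_hi &= vb <= cap_b
        thresholds[f"{gene_b}_cap"] = cap_b
    if cap_a is not None:
        b_hi &= va <= cap_a
        thresholds[f"{gene_a}_cap"] = cap_a
    overlap = a_hi & b_hi
    n_overlap = int(overlap.sum())
    if n_overlap:
        log.info("gate_biexpression: %d cells qualified for both gates; dropped",
                 n_overlap)
    a_hi &= ~overlap
    b_hi &= ~overlap
    if not a_hi.any() and not b_hi.any():
        warnings.warn("both gates are empty after exclusivity filtering",
                      stacklevel=2)
    labels = np.full(cells.n_obs, "ungated", dtype=object)
    labels[a_hi] = f"{gene_a}-hi"
    labels[b_hi] = f"{gene_b}-hi"
    return GateResult(pd.Series(labels, index=cells.obs_names, name="gate"),
                      gene_a, gene_b, q, thresholds, n_overlap)


def compare_gated_expression(gate: GateResult, cells: ad.AnnData, gene: str,
                             layer: str | None = None):
    """Expression of ``gene`` in the two gated populations + Mann-Whitney U.

    Returns ``(values_a, values_b, U, p)`` for the A-high and B-high gates.
    """
    v = gene_vector(cells, gene, layer=layer)
    in_a = (gate.labels == f"{gate.gene_a}-hi").to_numpy()
    in_b = (gate.labels == f"{gate.gene_b}-hi").to_numpy()
    if not in_a.any() or not in_b.any():
        raise ValidationError("both gates must be non-empty")
    u, p = mannwhitney_u(v[in_a], v[in_b])
    return v[in_a], v[in_b], u, p


def comp_positive_fraction(cells: ad.AnnData, population="fibroblast",
                           gene: str = "COMP") -> float:
    """Percent of the population with a raw count > 0 for ``gene``.

    Positivity is on raw counts by definition, so the value is invariant to
    any normalization settings. Empty population -> NaN.
    """
    if isinstance(population, str):
        pop = (cells.obs["cell_type"].astype(str) == population).to_numpy()
    elif population is None:
        pop = np.ones(cells.n_obs, dtype=bool)
    else:
        pop = np.asarray(population, dtype=bool)
    if not pop.any():
        return float("nan")
    v = gene_vector(cells, gene)
    return 100.0 * float((v[pop] > 0).mean())


def paired_delta(metric_pre: float, metric_post: float,
                 stability_threshold: float = 1.0):
    """Post-minus-pre change and the stability flag (|delta| < threshold)."""
    delta = metric_post - metric_pre
    return float(delta), bool(abs(delta) < stability_threshold)


def longitudinal_table(per_sample: pd.DataFrame, meta: pd.DataFrame,
                       stability_threshold: float = 1.0) -> pd.DataFrame:
    """Assemble one row per patient from per-sample metrics.

    ``per_sample`` is indexed by sample_id with columns ``comp_positive`` and
    (optionally) ``comphi_density``; ``meta`` supplies patient/timepoint/
    treatment/remission. Patients missing a timepoint are skipped with a
    warning.
    """
    m = meta.set_index("sample_id")
    rows = []
    for pid, grp in m.groupby("patient_id"):
        tp = grp.reset_index().set_index("timepoint")
        if not {"pre", "post"}.issubset(tp.index):
            warnings.warn(f"patient {pid}: missing timepoint; skipped", stacklevel=2)
            continue
        sid_pre, sid_post = tp.loc["pre", "sample_id"], tp.loc["post", "sample_id"]
        if sid_pre not in per_sample.index or sid_post not in per_sample.index:
            warnings.warn(f"patient {pid}: missing sample metrics; skipped",
                          stacklevel=2)
            continue
        pre, post = per_sample.loc[sid_pre], per_sample.loc[sid_post]
        delta, stable = paired_delta(pre["comp_positive"], post["comp_positive"],
                                     stability_threshold)
        row = {
            "patient_id": pid,
            "treatment": tp.loc["pre", "treatment"],
            "remission": tp.loc["pre", "remission"],
            "comp_positive_pre": float(pre["comp_positive"]),
            "comp_positive_post": float(post["comp_positive"]),
            "delta_comp_positive": delta,
            "stable": stable,
        }
        if "comphi_density" in per_sample.columns:
            row["comphi_density_pre"] = float(pre["comphi_density"])
            row["comphi_density_post"] = float(post["comphi_density"])
        rows.append(row)
    return pd.DataFrame(rows)


def delta_density_correlation(records: pd.DataFrame,
                              density: str = "post") -> tuple[float, float]:
    """Pearson correlation between delta %COMP+ fibroblasts and COMP-high
    region cell density across patients.

    ``density`` selects the post-treatment density (default) or the pre/post
    change (``"delta"``).
    """
    if density == "post":
        dens = records["comphi_density_post"]
    elif density == "delta":
        dens = records["comphi_density_post"] - records["comphi_density_pre"]
    else:
        raise ValueError("density must be 'post' or 'delta'")
    complete = records["delta_comp_positive"].notna() & dens.notna()
    if complete.sum() < 3:
        raise ValidationError("need at least 3 complete patient records")
    return pearson_r(records.loc[complete, "delta_comp_positive"], dens[complete])


def immune_abundance_change(cells_by_sample: dict[str, ad.AnnData],
                            meta: pd.DataFrame) -> pd.DataFrame:
    """Per-patient pre/post proportions of each immune cell type.

    Proportions are of all cells in the sample. Returns a tidy frame with one
    row per (patient, immune type): pre, post and the paired difference.
    Unpaired samples are skipped with a warning.
    """
    props = {}
    for sid, cells in cells_by_sample.items():
        ct = cells.obs["cell_type"].astype(str)
        props[sid] = {t: float((ct == t).mean()) for t in IMMUNE_TYPES}
    m = meta.set_index("sample_id")
    rows = []
    for pid, grp in m.groupby("patient_id"):
        tp = grp.reset_index().set_index("timepoint")
        if not {"pre", "post"}.issubset(tp.index):
            warnings.warn(f"patient {pid}: unpaired; skipped", stacklevel=2)
            continue
        pre_id, post_id = tp.loc["pre", "sample_id"], tp.loc["post", "sample_id"]
        if pre_id not in props or post_id not in props:
            warnings.warn(f"patient {pid}: missing sample; skipped", stacklevel=2)
            continue
        for t in IMMUNE_TYPES:
            rows.append({
                "patient_id": pid, "immune_type": t,
                "prop_pre": props[pre_id][t], "prop_post": props[post_id][t],
                "difference": props[post_id][t] - props[pre_id][t],
            })
    return pd.DataFrame(rows)
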