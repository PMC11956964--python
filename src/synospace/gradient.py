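"""Endothelial-distance gradient profiling.

Computes each cell's Euclidean distance to the nearest reference cell
(endothelial by default), bins expression against that distance in half-open
~23 um bins (about one cell layer), and tests whether high-expressing cells
sit nearer to or farther from the reference population than low-expressing
cells (top vs bottom expression quantiles, two-sided Mann-Whitney U on the
distance distributions).
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import spearmanr

from ._stats import mannwhitney_u
from .io import ValidationError, gene_vector

__all__ = [
    "GradientProfile",
    "nearest_reference_distance",
    "expression_vs_distance",
    "quantile_distance_test",
    "compare_profiles",
    "compare_gated_distances",
]


@dataclass
class GradientProfile:
    """Binned expression-vs-distance profile for one gene."""

    gene: str
    table: pd.DataFrame   # bin_lo, bin_hi, mean, sd, n, low_n flag
    bin_width: float

    def spearman(self) -> float:
        """Spearman rho of bin mean vs bin center over adequately filled bins."""
        t = self.table[~self.table["low_n"]]
        if len(t) < 3:
            return float("nan")
        rho, _ = spearmanr((t["bin_lo"] + t["bin_hi"]) / 2.0, t["mean"])
        return float(rho)


def nearest_reference_distance(cells: ad.AnnData,
                               reference_type: str = "endothelial") -> np.ndarray:
    """Per-cell Euclidean distance (um) to the nearest reference-typed cell.

    Reference cells are their own nearest reference, so they get distance 0.
    """
    if "cell_type" not in cells.obs:
        raise ValidationError("cell types must be assigned first")
    ref = (cells.obs["cell_type"].astype(str) == reference_type).to_numpy()
    if not ref.any():
        raise ValidationError(f"no cells of reference type {reference_type!r}")
    xy = cells.obs[["x", "y"]].to_numpy(dtype=float)
    d, _ = cKDTree(xy[ref]).query(xy)
    return np.asarray(d, dtype=float)


def expression_vs_distance(cells: ad.AnnData, gene: str,
                           distances: np.ndarray | None = None,
                           population: np.ndarray | str | None = "fibroblast",
                           bin_width: float = 23.0,
                           max_distance: float | None = None,
                           n_min: int = 10,
                           layer: str | None = "lognorm",
                           values: np.ndarray | None = None) -> GradientProfile:
    """Mean/sd/n of expression per half-open distance bin ``[lo, hi)``.

    ``population`` selects the analyzed cells (a cell-type name or a boolean
    mask; None for all). ``values`` overrides the expression vector (defaults
    to the normalized layer, computing it if absent). The sd is the population
    standard deviation (ribbon = one sd). Bins with fewer than ``n_min``
    cells are flagged ``low_n``.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if distances is None:
        distances = nearest_reference_distance(cells)
    if isinstance(population, str):
        pop = (cells.obs["cell_type"].astype(str) == population).to_numpy()
    elif population is None:
        pop = np.ones(cells.n_obs, dtype=bool)
    else:
        pop = np.asarray(population, dtype=bool)
    if values is None:
        if layer is not None and layer not in cells.layers:
            from .preprocess import normalize

            normalize(cells, layer=layer)
        values = gene_vector(cells, gene, layer=layer)
    d = np.asarray(distances, dtype=float)[pop]
    v = np.asarray(values, dtype=float)[pop]
    top = max_distance if max_distance is not None else (d.max() if len(d) else 0.0)
    n_bins = max(1, int(np.floor(top / bin_width)) + 1)
    edges = np.arange(n_bins + 1) * bin_width
    idx = np.digitize(d, edges) - 1
    rows = []
    for b in range(len(edges) - 1):
        m = idx == b
        n = int(m.sum())
        rows.append({
            "bin_lo": edges[b], "bin_hi": edges[b + 1],
            "mean": float(v[m].mean()) if n else float("nan"),
            "sd": float(v[m].std()) if n else float("nan"),
            "n": n, "low_n": n < n_min,
        })
    table = pd.DataFrame(rows)
    if max_distance is None:
        assert int(table["n"].sum()) == int(pop.sum())
    return GradientProfile(gene, table, bin_width)


def quantile_distance_test(cells: ad.AnnData, gene: str,
                           distances: np.ndarray | None = None,
                           population: np.ndarray | str | None = "fibroblast",
                           q: float = 0.25,
                           expressing_only: bool = True,
                           values: np.ndarray | None = None):
    """Nearest-reference distances of top- vs bottom-quantile expressers.

    Among analyzed cells (expression > 0 by default), the top group is
    ``expr >= (1-q) quantile`` (boundary ties included in the top group) and
    the bottom group ``expr <= q quantile``. Returns
    ``(median_top, median_bottom, U, p)``.
    """
    if not 0 < q < 0.5:
        raise ValueError("q must lie in (0, 0.5)")
    if distances is None:
        distances = nearest_reference_distance(cells)
    if isinstance(population, str):
        pop = (cells.obs["cell_type"].astype(str) == population).to_numpy()
    elif population is None:
        pop = np.ones(len(np.asarray(distances)), dtype=bool)
    else:
        pop = np.asarray(population, dtype=bool)
    if values is None:
        values = gene_vector(cells, gene)
    v = np.asarray(values, dtype=float)[pop]
    d = np.asarray(distances, dtype=float)[pop]
    if expressing_only:
        expr = v > 0
        v, d = v[expr], d[expr]
    if len(v) == 0 or np.ptp(v) == 0:
        raise ValidationError(
            f"expression of {gene} is degenerate; quantile groups undefined")
    lo_thr = np.quantile(v, q)
    hi_thr = np.quantile(v, 1.0 - q)
    bottom = v <= lo_thr
    top = v >= hi_thr
    overlap = top & bottom
    top &= ~overlap
    bottom &= ~overlap
    if top.sum() < 2 or bottom.sum() < 2:
        raise ValidationError("fewer than 2 cells in a quantile group")
    u, p = mannwhitney_u(d[top], d[bottom])
    return float(np.median(d[top])), float(np.median(d[bottom])), u, p


def compare_profiles(profile_a: GradientProfile, profile_b: GradientProfile,
                     values_a: np.ndarray | None = None,
                     values_b: np.ndarray | None = None):
    """Per-bin mean differences between two conditions plus a global test.

    The profiles must share a bin scheme. When the per-cell expression
    vectors of both conditions are supplied, a two-sided Mann-Whitney U test
    on them gives the condition-level contrast. Returns
    ``(bin_table, U, p)``; U and p are NaN without per-cell values.
    """
    a, b = profile_a.table, profile_b.table
    n = min(len(a), len(b))
    if not np.allclose(a["bin_lo"].to_numpy()[:n], b["bin_lo"].to_numpy()[:n]):
        raise ValidationError("profiles use different bin schemes")
    out = pd.DataFrame({
        "bin_lo": a["bin_lo"].to_numpy()[:n],
        "bin_hi": a["bin_hi"].to_numpy()[:n],
        "mean_a": a["mean"].to_numpy()[:n],
        "mean_b": b["mean"].to_numpy()[:n],
    })
    out["difference"] = out["mean_a"] - out["mean_b"]
    if values_a is not None and values_b is not None:
        u, p = mannwhitney_u(np.asarray(values_a, dtype=float),
                             np.asarray(values_b, dtype=float))
    else:
        u, p = float("nan"), float("nan")
    return out, u, p


def plot_profile(profiles, ax=None, colors=None):
    """Line-and-ribbon plot of one or more gradient profiles.

    The solid line is the per-bin mean, the ribbon one population standard
    deviation. Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    if isinstance(profiles, GradientProfile):
        profiles = [profiles]
    for i, prof in enumerate(profiles):
        t = prof.table[prof.table["n"] > 0]
        mid = (t["bin_lo"] + t["bin_hi"]) / 2.0
        color = None if colors is None else colors[i]
        line, = ax.plot(mid, t["mean"], label=prof.gene, color=color)
        ax.fill_between(mid, t["mean"] - t["sd"], t["mean"] + t["sd"],
                        alpha=0.2, color=line.get_color())
    ax.set_xlabel("distance to nearest endothelial cell (µm)")
    ax.set_ylabel("expression")
    ax.legend(frameon=False)
    return ax


def compare_gated_distances(distances_a, distances_b):
    """Two-sided Mann-Whitney U on nearest-reference distances of gated-high
    cells between two conditions (e.g. COMP-high cells, control vs knockdown).

    Returns ``(median_a, median_b, U, p)``.
    """
    da = np.asarray(distances_a, dtype=float)
    db = np.asarray(distances_b, dtype=float)
    u, p = mannwhitney_u(da, db)
    return float(np.median(da)), float(np.median(db)), u, p
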