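"""QC, normalization, marker-based typing, niche segmentation and sample-level
composition statistics.

Niche segmentation here deliberately replaces embedding-based tooling with a
transparent two-step procedure: spatially contiguous patches of ~k cells are
grown on the k-nearest-neighbour graph, summarized by their cell-type
composition, and the patch compositions are Leiden-clustered; clusters are
then named against a label dictionary of niche archetypes. The niche taxonomy
(fibroblast-rich, vascular, stromal-adipose, liningF, liningM, immuneT,
immuneP), not any particular embedding, is the analysis object.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import anndata as ad
import igraph
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.cluster import hierarchy
from scipy.spatial import ConvexHull, QhullError, cKDTree
from sklearn.cluster import KMeans

from ._stats import mannwhitney_u, pearson_r
from .io import ConfigError, NICHE_TYPES, ValidationError, gene_vector

log = logging.getLogger(__name__)

__all__ = [
    "MarkerRule",
    "DEFAULT_MARKER_RULES",
    "DEFAULT_SUBTYPE_MARKERS",
    "NICHE_LABEL_WEIGHTS",
    "NicheSummary",
    "qc_filter",
    "normalize",
    "assign_cell_types",
    "classify_fibroblast_subtypes",
    "segment_niches",
    "niche_summary",
    "cluster_samples",
    "linkage_to_newick",
    "correlate_niche_areas",
    "compare_marker_by_group",
]


# ---------------------------------------------------------------------------
# QC and normalization


def qc_filter(cells: ad.AnnData, min_features: int = 50) -> ad.AnnData:
    """Drop cells detecting ``min_features`` or fewer gene species.

    Retains exactly the cells with ``n_features > min_features``; idempotent.
    """
    keep = cells.obs["n_features"].to_numpy() > min_features
    n_removed = int((~keep).sum())
    log.info("qc_filter: removed %d of %d cells (n_features <= %d)",
             n_removed, cells.n_obs, min_features)
    if keep.sum() == 0:
        warnings.warn("qc_filter removed every cell", stacklevel=2)
    return cells[keep].copy()


def normalize(cells: ad.AnnData, layer: str = "lognorm"):
    """Per-sample median-scaled log normalization.

    For a cell with total count ``t`` in sample ``s`` with median total ``m_s``
    the normalized value of a count ``c`` is ``log(1 + c * m_s / t)``. The
    result is stored in ``cells.layers[layer]`` and returned (sparse if the
    counts are sparse). Cells with zero total counts are left at zero with a
    warning. The rule is invariant to a uniform rescaling of all counts in a
    sample and monotone in each cell's counts.
    """
    totals = cells.obs["total_counts"].to_numpy(dtype=float)
    sample = cells.obs["sample_id"].to_numpy()
    factor = np.zeros(cells.n_obs)
    for s in pd.unique(sample):
        m = sample == s
        pos = m & (totals > 0)
        if pos.any():
            med = float(np.median(totals[pos]))
            factor[pos] = med / totals[pos]
    if (totals == 0).any():
        warnings.warn(f"{int((totals == 0).sum())} zero-total cells left unnormalized",
                      stacklevel=2)
    X = cells.X
    if sp.issparse(X):
        out = X.tocsr().astype(float).copy()
        out.data *= np.repeat(factor, np.diff(out.indptr))
        out.data = np.log1p(out.data)
    else:
        out = np.log1p(np.asarray(X, dtype=float) * factor[:, None])
    cells.layers[layer] = out
    return out


# ---------------------------------------------------------------------------
# marker-based typing


@dataclass(frozen=True)
class MarkerRule:
    """Markers scored for one label plus genes that must be detected (>0)."""

    markers: tuple[str, ...]
    require_positive: tuple[str, ...] = ()


DEFAULT_MARKER_RULES: dict[str, MarkerRule] = {
    "endothelial": MarkerRule(("PECAM1", "PLVAP", "DLL4", "HEY1"), ("PECAM1",)),
    "mural": MarkerRule(("ACTA2", "RGS5"), ("ACTA2",)),
    "fibroblast": MarkerRule(("PDGFRB", "NOTCH2", "COL1A1", "COL5A1"),
                             ("PDGFRB", "NOTCH2")),
    "T": MarkerRule(("CD3E",), ("CD3E",)),
    "B": MarkerRule(("MS4A1",), ("MS4A1",)),
    "plasma": MarkerRule(("MZB1",), ("MZB1",)),
    "myeloid": MarkerRule(("HTRA1",), ("HTRA1",)),
    "adipocyte": MarkerRule(("ADIPOQ",), ("ADIPOQ",)),
}

DEFAULT_SUBTYPE_MARKERS: dict[str, tuple[str, ...]] = {
    "lining": ("CD55",),
    "fibrogenic": ("COL6A1", "COL8A1", "COMP"),
    "inflammatory": ("CXCL12", "SFRP1"),
    "vascular": ("NOTCH3", "THY1", "COL15A1"),
    "L1CAM": ("L1CAM",),
}


def _marker_scores(cells: ad.AnnData, genes: tuple[str, ...], layer: str) -> np.ndarray:
    missing = [g for g in genes if g not in cells.var_names]
    if missing:
        raise ConfigError(f"marker rule references genes not on panel: {missing}")
    cols = np.column_stack([gene_vector(cells, g, layer=layer) for g in genes])
    return cols.mean(axis=1)


def assign_cell_types(cells: ad.AnnData,
                      marker_rules: dict[str, MarkerRule] | None = None,
                      layer: str = "lognorm",
                      min_score: float = 0.0) -> ad.AnnData:
    """Label each cell with the best-scoring marker rule.

    The score of a rule is the mean normalized expression of its markers; a
    rule is eligible only if every ``require_positive`` gene has a raw count
    > 0. Cells with no eligible rule, an all-zero best score, or a best score
    at or below ``min_score`` become ``other`` (a confidence floor keeps
    stray single-count marker detections from minting immune cells).
    Argmax ties break by rule order.
    """
    rules = marker_rules or DEFAULT_MARKER_RULES
    if layer not in cells.layers:
        normalize(cells, layer=layer)
    n = cells.n_obs
    names = list(rules)
    scores = np.zeros((n, len(rules)))
    eligible = np.ones((n, len(rules)), dtype=bool)
    for j, (name, rule) in enumerate(rules.items()):
        scores[:, j] = _marker_scores(cells, rule.markers, layer)
        for g in rule.require_positive:
            eligible[:, j] &= gene_vector(cells, g) > 0
    scores[~eligible] = -np.inf
    best = np.argmax(scores, axis=1)
    best_score = scores[np.arange(n), best]
    labels = np.array([names[j] for j in best], dtype=object)
    labels[~np.isfinite(best_score) | (best_score <= max(0.0, min_score))] = "other"
    cells.obs["cell_type"] = pd.Categorical(labels, categories=list(rules) + ["other"])
    return cells


def classify_fibroblast_subtypes(cells: ad.AnnData,
                                 subtype_markers: dict[str, tuple[str, ...]] | None = None,
                                 lowrna_threshold: int = 8,
                                 layer: str = "lognorm") -> ad.AnnData:
    """Subtype fibroblasts: below the detection threshold -> ``lowRNA``, else
    argmax of mean normalized subtype marker expression."""
    markers = subtype_markers or DEFAULT_SUBTYPE_MARKERS
    if "cell_type" not in cells.obs:
        raise ValidationError("assign_cell_types must run before subtyping")
    if layer not in cells.layers:
        normalize(cells, layer=layer)
    fib = (cells.obs["cell_type"].astype(str) == "fibroblast").to_numpy()
    if (~fib).any():
        log.info("classify_fibroblast_subtypes: ignoring %d non-fibroblast cells",
                 int((~fib).sum()))
    names = list(markers)
    scores = np.column_stack([_marker_scores(cells, m, layer) for m in markers.values()])
    best = np.array([names[j] for j in np.argmax(scores, axis=1)], dtype=object)
    labels = np.full(cells.n_obs, "none", dtype=object)
    labels[fib] = best[fib]
    low = fib & (cells.obs["n_features"].to_numpy() < lowrna_threshold)
    labels[low] = "lowRNA"
    cells.obs["fibro_subtype"] = pd.Categorical(labels, categories=names + ["lowRNA", "none"])
    return cells


# ---------------------------------------------------------------------------
# niche segmentation

#: composition categories used to summarize patches
_COMP_CATEGORIES = ("endothelial", "mural", "fib_sublining", "fib_lining",
                    "T", "B", "plasma", "myeloid", "adipocyte", "other")

#: label dictionary: weights applied to a cluster's mean composition vector
NICHE_LABEL_WEIGHTS: dict[str, dict[str, float]] = {
    "fibroblast-rich": {"fib_sublining": 1.0},
    "vascular": {"endothelial": 3.0, "mural": 3.0},
    "stromal-adipose": {"adipocyte": 4.0},
    "liningF": {"fib_lining": 2.5},
    "liningM": {"myeloid": 2.0, "fib_lining": 0.5},
    "immuneT": {"T": 2.0, "B": 2.0},
    "immuneP": {"plasma": 3.0},
}


def _composition_category(cells: ad.AnnData) -> np.ndarray:
    ctype = cells.obs["cell_type"].astype(str).to_numpy().copy()
    fib = ctype == "fibroblast"
    if "fibro_subtype" in cells.obs:
        lining = fib & (cells.obs["fibro_subtype"].astype(str) == "lining").to_numpy()
    else:
        lining = np.zeros(cells.n_obs, dtype=bool)
    out = ctype.astype(object)
    out[fib] = "fib_sublining"
    out[lining] = "fib_lining"
    known = set(_COMP_CATEGORIES)
    out[[c not in known for c in out]] = "other"
    return out


def _grow_patches(xy: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """Compact, spatially contiguous patches of ~k cells each.

    k-means on the centroid coordinates with n/k centers yields Voronoi
    patches that adapt to local density (dense aggregates get spatially
    smaller patches), which keeps patch compositions pure near niche
    boundaries.
    """
    n_clusters = max(1, len(xy) // k)
    if n_clusters == 1:
        return np.zeros(len(xy), dtype=int)
    km = KMeans(n_clusters=n_clusters, n_init=3, random_state=seed)
    return km.fit_predict(xy)


def _label_cluster(comp: pd.Series) -> str:
    scores = {
        label: sum(w * comp.get(cat, 0.0) for cat, w in weights.items())
        for label, weights in NICHE_LABEL_WEIGHTS.items()
    }
    return max(scores, key=lambda lab: (scores[lab], -list(scores).index(lab)))


def segment_niches(cells: ad.AnnData, patch_size: int = 30,
                   resolution: float = 0.5, knn: int = 10,
                   seed: int = 0) -> ad.AnnData:
    """Partition cells into spatial patches, cluster patch compositions with
    Leiden, and name clusters against the niche label dictionary.

    Every cell receives a ``niche_id`` (its patch) and a ``niche_type``.
    """
    if "cell_type" not in cells.obs:
        raise ValidationError("assign_cell_types must run before segment_niches")
    niche_id = np.empty(cells.n_obs, dtype=object)
    niche_type = np.empty(cells.n_obs, dtype=object)
    for s in pd.unique(cells.obs["sample_id"]):
        mask = (cells.obs["sample_id"] == s).to_numpy()
        xy = cells.obs.loc[mask, ["x", "y"]].to_numpy(dtype=float)
        if patch_size > mask.sum():
            warnings.warn(f"patch size {patch_size} exceeds sample size "
                          f"{int(mask.sum())}; one patch", stacklevel=2)
        patch = _grow_patches(xy, patch_size, seed=seed)
        cats = _composition_category(cells[mask])
        comp = (
            pd.crosstab(patch, cats, normalize="index")
            .reindex(columns=list(_COMP_CATEGORIES), fill_value=0.0)
        )
        labels = _cluster_compositions(comp, resolution, knn, seed)
        cluster_label = {
            cl: _label_cluster(comp[labels == cl].mean(axis=0))
            for cl in np.unique(labels)
        }
        niche_id[mask] = np.array([f"{s}_patch{p:04d}" for p in patch], dtype=object)
        niche_type[mask] = np.array([cluster_label[labels[p]] for p in patch],
                                    dtype=object)
    cells.obs["niche_id"] = niche_id
    cells.obs["niche_type"] = pd.Categorical(niche_type, categories=list(NICHE_TYPES))
    return cells


def _cluster_compositions(comp: pd.DataFrame, resolution: float, knn: int,
                          seed: int) -> np.ndarray:
    n = len(comp)
    if n <= 2:
        return np.zeros(n, dtype=int)
    k = min(knn, n - 1)
    X = comp.to_numpy()
    dist, nbrs = cKDTree(X).query(X, k=k + 1)
    # Gaussian edge weights at a local scale: edges between unlike
    # compositions carry negligible weight, so small but distinct patch
    # groups are not absorbed by their nearest large cluster.
    sigma = max(float(np.median(dist[:, min(3, k)])), 1e-6)
    weights_by_edge: dict[tuple[int, int], float] = {}
    for i, (drow, row) in enumerate(zip(dist, nbrs)):
        for d, j in zip(drow[1:], row[1:]):
            e = (min(i, int(j)), max(i, int(j)))
            weights_by_edge[e] = float(np.exp(-((d / sigma) ** 2)))
    edges = sorted(weights_by_edge)
    g = igraph.Graph(n=n, edges=edges)
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        weights=[weights_by_edge[e] for e in edges],
        resolution_parameter=resolution, seed=seed, n_iterations=5,
    )
    return np.asarray(part.membership)


# ---------------------------------------------------------------------------
# niche-level summaries


@dataclass
class NicheSummary:
    """Per-sample niche tissue-area fractions and per-niche composition."""

    area_fractions: pd.DataFrame     # samples x niche types, rows sum to 1
    composition: pd.DataFrame        # niche type x cell type, rows sum to 1
    niche_counts: pd.DataFrame       # samples x niche types, patch counts


def _patch_area(xy: np.ndarray, per_cell_area: float) -> float:
    if len(xy) >= 3:
        try:
            hull = ConvexHull(xy)
            if hull.volume > 0:
                return float(hull.volume)  # 2-D: volume is the polygon area
        except QhullError:
            pass
    return float(len(xy) * per_cell_area)


def niche_summary(cells: ad.AnnData, per_cell_area: float = 100.0) -> NicheSummary:
    """Area per niche = sum of patch convex-hull areas (um^2); degenerate
    patches fall back to ``n_cells * per_cell_area``."""
    if "niche_id" not in cells.obs:
        raise ValidationError("segment_niches must run before niche_summary")
    obs = cells.obs
    rows = []
    for (s, nid), idx in obs.groupby(["sample_id", "niche_id"], observed=True).groups.items():
        sub = obs.loc[idx]
        rows.append({
            "sample_id": s, "niche_id": nid,
            "niche_type": str(sub["niche_type"].iloc[0]),
            "area": _patch_area(sub[["x", "y"]].to_numpy(dtype=float), per_cell_area),
        })
    patches = pd.DataFrame(rows)
    area = (patches.pivot_table(index="sample_id", columns="niche_type",
                                values="area", aggfunc="sum", fill_value=0.0)
            .reindex(columns=list(NICHE_TYPES), fill_value=0.0))
    fractions = area.div(area.sum(axis=1), axis=0)
    counts = (patches.pivot_table(index="sample_id", columns="niche_type",
                                  values="niche_id", aggfunc="count", fill_value=0)
              .reindex(columns=list(NICHE_TYPES), fill_value=0))
    comp = (pd.crosstab(obs["niche_type"], obs["cell_type"], normalize="index")
            if "cell_type" in obs else pd.DataFrame())
    return NicheSummary(fractions, comp, counts)


def linkage_to_newick(Z: np.ndarray, names: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string."""
    tree = hierarchy.to_tree(Z)

    def walk(node, parent_dist) -> str:
        length = parent_dist - node.dist
        if node.is_leaf():
            return f"{names[node.id]}:{length:.6g}"
        return (f"({walk(node.left, node.dist)},{walk(node.right, node.dist)})"
                f":{length:.6g}")

    return walk(tree, tree.dist) + ";"


def cluster_samples(area_matrix: pd.DataFrame, n_groups: int):
    """Ward hierarchical clustering of samples on niche-area fractions.

    Returns ``(labels, linkage, newick)``; labels are 1..n_groups in order of
    first appearance.
    """
    if n_groups > len(area_matrix):
        raise ValueError("n_groups exceeds number of samples")
    Z = hierarchy.linkage(area_matrix.to_numpy(), method="ward")
    labels = hierarchy.fcluster(Z, t=n_groups, criterion="maxclust")
    return (pd.Series(labels, index=area_matrix.index, name="group"),
            Z, linkage_to_newick(Z, list(area_matrix.index.astype(str))))


def correlate_niche_areas(area_matrix: pd.DataFrame, set_a: list[str],
                          niche_b: str) -> tuple[float, float]:
    """Pearson correlation between summed area fractions of ``set_a`` and the
    area fraction of ``niche_b`` across samples."""
    a = area_matrix[list(set_a)].sum(axis=1).to_numpy()
    b = area_matrix[niche_b].to_numpy()
    return pearson_r(a, b)


def compare_marker_by_group(cells: ad.AnnData, meta: pd.DataFrame, gene: str,
                            grouping: str, population: str = "fibroblast",
                            layer: str = "lognorm"):
    """Per-sample mean normalized expression of ``gene`` in ``population``
    cells, compared between two metadata groups with a two-sided
    Mann-Whitney U test.

    Returns ``(per_sample, U, p)`` where ``per_sample`` maps sample to
    (group, mean value).
    """
    if layer not in cells.layers:
        normalize(cells, layer=layer)
    vals = gene_vector(cells, gene, layer=layer)
    pop = (cells.obs["cell_type"].astype(str) == population).to_numpy() \
        if population else np.ones(cells.n_obs, dtype=bool)
    sample_ids = cells.obs["sample_id"].to_numpy()
    per_sample = {}
    for s in pd.unique(sample_ids):
        m = pop & (sample_ids == s)
        if m.any():
            per_sample[s] = float(vals[m].mean())
    meta_idx = meta.set_index("sample_id")[grouping]
    tidy = pd.DataFrame({
        "sample_id": list(per_sample),
        "group": [meta_idx.get(s) for s in per_sample],
        "mean_expr": list(per_sample.values()),
    }).dropna(subset=["group"])
    groups = tidy.groupby("group")["mean_expr"].apply(list)
    if len(groups) != 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need exactly two groups with >= 2 samples each")
    u, p = mannwhitney_u(groups.iloc[0], groups.iloc[1])
    return tidy, u, p
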