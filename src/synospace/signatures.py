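"""Rank-based per-cell gene-set scoring and niche-level signature statistics.

The per-cell score is the UCell-style capped-rank statistic: within each cell
all panel genes are ranked by decreasing expression (average ranks on ties),
ranks are capped at ``rmax + 1``, and with ``n`` signature genes on the panel

    U' = sum(ranks of signature genes) - n (n + 1) / 2
    score = max(0, 1 - U' / (n * rmax))

so a cell whose signature genes occupy the top ``n`` ranks scores 1 and a
cell whose signature genes all fall beyond the rank ceiling scores 0. The
score depends on expression only through within-cell ranks, so it is
invariant to any strictly increasing per-cell transform (and hence to the
choice of normalization).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import rankdata

from ._stats import mannwhitney_u, pearson_r
from .io import Signature, ValidationError, gene_vector

__all__ = [
    "ScoreVector",
    "rank_signature_score",
    "top_fraction_subset",
    "score_niches",
    "downsampled_niche_comparison",
    "compare_all_niche_types",
    "notch_tgfbr3_correlation",
]


@dataclass
class ScoreVector:
    """Signature scores for a set of units (cells or niches)."""

    unit: str                 # "cell" | "niche"
    ids: pd.Index
    signature: str
    scores: np.ndarray        # in [0, 1]

    def __post_init__(self) -> None:
        finite = self.scores[np.isfinite(self.scores)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValidationError("scores must lie in [0, 1]")

    def to_series(self) -> pd.Series:
        return pd.Series(self.scores, index=self.ids, name=self.signature)


def rank_signature_score(expr, sig: Signature, genes=None,
                         unit_ids=None) -> ScoreVector:
    """Score every cell of an expression matrix against a signature.

    ``expr`` may be an AnnData (uses ``X``; ranks are transform-invariant so
    counts and log-normalized values give identical scores) or a cells x genes
    array with ``genes`` naming the columns.
    """
    if isinstance(expr, ad.AnnData):
        genes = list(expr.var_names)
        unit_ids = expr.obs_names
        M = expr.X
    else:
        if genes is None:
            raise ValueError("genes must be provided with a bare matrix")
        M = expr
        unit_ids = pd.Index(unit_ids if unit_ids is not None else range(M.shape[0]))
    M = np.asarray(M.todense() if sp.issparse(M) else M, dtype=float)
    gene_pos = {g: j for j, g in enumerate(genes)}
    sig_idx = [gene_pos[g] for g in sig.genes if g in gene_pos]
    if not sig_idx:
        missing = list(sig.genes)
        raise ValidationError(
            f"signature {sig.name!r}: none of its genes are on the panel: {missing}")
    n = len(sig_idx)
    rmax = min(sig.rmax, len(genes))
    # ranks by decreasing expression, average ranks on ties, capped
    ranks = rankdata(-M, axis=1, method="average")
    ranks = np.minimum(ranks, rmax + 1)
    u_prime = ranks[:, sig_idx].sum(axis=1) - n * (n + 1) / 2.0
    scores = np.maximum(0.0, 1.0 - u_prime / (n * rmax))
    return ScoreVector("cell", pd.Index(unit_ids), sig.name, scores)


def top_fraction_subset(scores: ScoreVector, q: float = 0.10):
    """Ids with score strictly above the empirical (1 - q) quantile.

    Returns ``(ids, threshold)``. With heavy ties at the threshold the subset
    can be smaller than ``q * n`` (strict inequality); an all-equal score
    vector yields an empty subset with a warning.
    """
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    thr = float(np.quantile(scores.scores, 1.0 - q))
    keep = scores.scores > thr
    if not keep.any():
        warnings.warn("top_fraction_subset: no scores strictly above the "
                      "threshold (all tied?)", stacklevel=2)
    return scores.ids[keep], thr


def score_niches(cells: ad.AnnData, sig: Signature,
                 cell_scores: ScoreVector | None = None,
                 by: str = "niche_id") -> pd.DataFrame:
    """Mean per-cell signature score per niche.

    Returns a tidy frame (niche id, niche type, sample, n cells, score).
    Empty niches cannot occur by construction; niches are whatever ``by``
    indexes (patches by default).
    """
    if by not in cells.obs:
        raise ValidationError(f"cells lack a {by!r} column")
    sc = cell_scores if cell_scores is not None else rank_signature_score(cells, sig)
    df = pd.DataFrame({
        "niche_id": cells.obs[by].to_numpy(),
        "score": sc.scores,
        "sample_id": cells.obs["sample_id"].to_numpy(),
    })
    if "niche_type" in cells.obs:
        df["niche_type"] = cells.obs["niche_type"].astype(str).to_numpy()
    grouped = df.groupby("niche_id", observed=True).agg(
        score=("score", "mean"), n_cells=("score", "size"),
        sample_id=("sample_id", "first"),
        **({"niche_type": ("niche_type", "first")} if "niche_type" in df else {}),
    ).reset_index()
    grouped["signature"] = sig.name
    return grouped


def downsampled_niche_comparison(niche_scores: pd.DataFrame, niche_type: str,
                                 n_draw: int = 500, seed: int = 0):
    """Compare one niche type's score distribution to all other niches using
    the down-sampled convention: draw ``n_draw`` scores from the focal type
    and ``n_draw`` from the rest (with replacement when a stratum is smaller,
    logged via warning), then a two-sided Mann-Whitney U test.

    Returns ``(U, p)``.
    """
    if niche_scores["niche_type"].nunique() < 2:
        raise ValidationError("need at least two niche types to compare")
    rng = np.random.default_rng(seed)
    focal = niche_scores.loc[niche_scores["niche_type"] == niche_type, "score"].to_numpy()
    other = niche_scores.loc[niche_scores["niche_type"] != niche_type, "score"].to_numpy()
    if len(focal) == 0:
        raise ValidationError(f"no niches of type {niche_type!r}")
    draws = []
    for pool in (focal, other):
        replace = len(pool) < n_draw
        if replace:
            warnings.warn(f"drawing {n_draw} from stratum of {len(pool)} "
                          "with replacement", stacklevel=2)
        draws.append(rng.choice(pool, size=n_draw, replace=replace))
    return mannwhitney_u(draws[0], draws[1])


def compare_all_niche_types(niche_scores: pd.DataFrame, n_draw: int = 500,
                            seed: int = 0) -> pd.DataFrame:
    """Down-sampled comparison for every niche type, Bonferroni-adjusted."""
    types = sorted(niche_scores["niche_type"].dropna().unique())
    rows = []
    for i, t in enumerate(types):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u, p = downsampled_niche_comparison(niche_scores, t, n_draw, seed + i)
        n_t = int((niche_scores["niche_type"] == t).sum())
        rows.append({"niche_type": t, "U": u, "p": p, "n_niches": n_t})
    out = pd.DataFrame(rows)
    out["padj"] = np.minimum(out["p"] * len(out), 1.0)
    return out


def notch_tgfbr3_correlation(cells: ad.AnnData, notch_sig: Signature,
                             gene: str = "TGFBR3",
                             vascular_label: str = "vascular",
                             layer: str = "lognorm",
                             min_niches: int = 3):
    """Per-sample Pearson correlation between the Notch-activation score of
    vascular niches and their mean normalized ``gene`` expression.

    Returns ``(per_sample, mean_r)`` where ``per_sample`` has one row per
    sample (R, p, n vascular niches); samples with fewer than ``min_niches``
    vascular niches or zero variance yield NaN.
    """
    if layer is not None and layer not in cells.layers:
        from .preprocess import normalize

        normalize(cells, layer=layer)
    vasc = (cells.obs["niche_type"].astype(str) == vascular_label).to_numpy()
    sub = cells[vasc]
    if sub.n_obs == 0:
        raise ValidationError(f"no cells in {vascular_label!r} niches")
    sc = rank_signature_score(sub, notch_sig)
    expr = gene_vector(sub, gene, layer=layer)
    df = pd.DataFrame({
        "sample_id": sub.obs["sample_id"].to_numpy(),
        "niche_id": sub.obs["niche_id"].to_numpy(),
        "score": sc.scores, "expr": expr,
    })
    per_niche = df.groupby(["sample_id", "niche_id"], observed=True).mean(numeric_only=True)
    rows = []
    for s, grp in per_niche.groupby(level="sample_id"):
        if len(grp) < min_niches:
            rows.append({"sample_id": s, "R": np.nan, "p": np.nan, "n_niches": len(grp)})
            continue
        r, p = pearson_r(grp["score"], grp["expr"])
        rows.append({"sample_id": s, "R": r, "p": p, "n_niches": len(grp)})
    per_sample = pd.DataFrame(rows)
    mean_r = float(np.nanmean(per_sample["R"])) if len(per_sample) else float("nan")
    return per_sample, mean_r
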