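"""Domain types and Xenium-style table input/output.

The in-memory cell container is an :class:`anndata.AnnData`:

* ``X`` — sparse (CSR) non-negative integer counts, cells x panel genes;
* ``obs`` — per-cell metadata: ``sample_id``, ``x``, ``y`` (micrometres, image
  convention: origin top-left, y increasing downward), derived ``n_features``
  and ``total_counts``, and the analysis labels ``cell_type``,
  ``fibro_subtype``, ``niche_id``, ``niche_type`` once assigned;
* ``var_names`` — the gene panel; ``obs_names`` — cell ids.

On-disk formats follow the platform's tabular exports (CSV or Parquet, chosen
by file extension) with the documented column mapping::

    cell tables:        cell_id, x_centroid -> x, y_centroid -> y, <gene> ...
    transcript tables:  feature_name -> gene, x_location -> x, y_location -> y

Transcript tables are plain :class:`pandas.DataFrame` objects with columns
``gene``, ``x``, ``y`` and ``sample_id``.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

__all__ = [
    "CELL_TYPES",
    "FIBRO_SUBTYPES",
    "NICHE_TYPES",
    "SchemaError",
    "ValidationError",
    "ConfigError",
    "GenePanel",
    "Signature",
    "PipelineConfig",
    "make_cell_table",
    "validate_cells",
    "make_transcript_table",
    "validate_transcripts",
    "validate_sample_meta",
    "read_cells",
    "write_cells",
    "read_transcripts",
    "write_transcripts",
    "load_signature",
    "gene_vector",
]

CELL_TYPES = (
    "endothelial", "mural", "fibroblast", "T", "B",
    "plasma", "myeloid", "adipocyte", "other",
)
FIBRO_SUBTYPES = (
    "lining", "fibrogenic", "inflammatory", "vascular", "L1CAM", "lowRNA", "none",
)
NICHE_TYPES = (
    "fibroblast-rich", "vascular", "stromal-adipose",
    "liningF", "liningM", "immuneT", "immuneP",
)

#: platform export column name -> internal name
CELL_COLUMN_MAP = {"x_centroid": "x", "y_centroid": "y"}
TRANSCRIPT_COLUMN_MAP = {"feature_name": "gene", "x_location": "x", "y_location": "y"}


class SchemaError(ValueError):
    """A table is missing required columns or has the wrong layout."""


class ValidationError(ValueError):
    """Table contents violate a domain invariant."""


class ConfigError(ValueError):
    """Invalid configuration value."""


@dataclass(frozen=True)
class GenePanel:
    """Ordered gene panel (e.g. a 5k discovery panel or a ~50-gene custom panel)."""

    genes: tuple[str, ...]
    panel_kind: str = "custom50"

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise ValidationError("gene panel is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("gene panel contains duplicate names")

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def __len__(self) -> int:
        return len(self.genes)

    def index(self, gene: str) -> int:
        return self.genes.index(gene)


@dataclass(frozen=True)
class Signature:
    """A named gene set scored with a capped-rank (UCell-style) statistic.

    ``rmax`` is the rank ceiling: genes ranked beyond it contribute the capped
    rank ``rmax + 1``. The effective ceiling used at scoring time is
    ``min(rmax, panel size)`` so that scores keep their full [0, 1] range on
    small targeted panels.
    """

    name: str
    genes: tuple[str, ...]
    rmax: int = 1500

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise ValidationError(f"signature {self.name!r} has no genes")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"signature {self.name!r} has duplicate genes")
        if self.rmax < len(self.genes):
            raise ValidationError("rank ceiling rmax must be >= number of signature genes")


@dataclass
class PipelineConfig:
    """Declarative analysis parameters shared by all stages.

    Thresholds that mirror printed constants of the underlying study design:
    ``qc_min_features`` (cells with <= 50 detected gene species are discarded
    on the 5k panel), ``hdr_mass`` (50% highest-density contour),
    ``gradient_bin_width`` (~23 um, one cell layer), ``gate_quantile`` (top
    quantile of expressing cells, default top 25%), ``delta_stability``
    (|delta %COMP+| < 1 percentage point counts as stable) and
    ``remission_das28`` (DAS28-ESR < 2.6).
    """

    qc_min_features: int = 50
    niche_patch_size: int = 15
    niche_resolution: float = 0.5
    niche_knn: int = 10
    kde_pixel_size: float = 10.0
    kde_bandwidth: float | None = None  # None -> normal-scale rule
    hdr_mass: float = 0.5
    gradient_bin_width: float = 23.0
    gate_quantile: float = 0.25
    gate_cap_postn: float | None = 3.5
    delta_stability: float = 1.0
    remission_das28: float = 2.6
    type_min_score: float = 0.8   # confidence floor for marker typing
    per_cell_area: float = 100.0  # um^2 fallback for degenerate patch hulls
    lowrna_features: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.qc_min_features < 0:
            raise ConfigError("qc_min_features must be non-negative")
        if not 0 < self.hdr_mass < 1:
            raise ConfigError("hdr_mass must lie in (0, 1)")
        if not 0 < self.gate_quantile < 1:
            raise ConfigError("gate_quantile must lie in (0, 1)")
        for name in ("niche_patch_size", "kde_pixel_size", "gradient_bin_width",
                     "delta_stability", "per_cell_area"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    def provenance(self) -> dict:
        """Config hash + seed recorded in every run's outputs."""
        blob = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True).encode()
        return {
            "config_sha256": hashlib.sha256(blob).hexdigest(),
            "seed": self.seed,
            "synospace_version": _version(),
        }


def _version() -> str:
    from synospace import __version__

    return __version__


# ---------------------------------------------------------------------------
# cell tables


def make_cell_table(
    counts,
    genes: Sequence[str],
    cell_id: Sequence,
    sample_id,
    x,
    y,
    **obs_columns,
) -> ad.AnnData:
    """Build and validate a cell table.

    ``counts`` may be dense or sparse; it is stored as CSR. Derived columns
    ``n_features`` and ``total_counts`` are always recomputed here.
    """
    X = sp.csr_matrix(counts)
    if X.shape[1] != len(genes):
        raise SchemaError(f"counts has {X.shape[1]} columns for {len(genes)} genes")
    obs = pd.DataFrame(index=pd.Index([str(c) for c in cell_id], name="cell_id"))
    if obs.index.has_duplicates:
        raise ValidationError("duplicate cell ids")
    obs["sample_id"] = np.broadcast_to(np.asarray(sample_id, dtype=object), (X.shape[0],))
    obs["x"] = np.asarray(x, dtype=float)
    obs["y"] = np.asarray(y, dtype=float)
    for key, val in obs_columns.items():
        obs[key] = val
    adata = ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=pd.Index(list(genes), name="gene")))
    _derive_counts_fields(adata)
    validate_cells(adata)
    return adata


def _derive_counts_fields(cells: ad.AnnData) -> None:
    X = cells.X
    cells.obs["n_features"] = np.asarray((X > 0).sum(axis=1)).ravel().astype(int)
    cells.obs["total_counts"] = np.asarray(X.sum(axis=1)).ravel().astype(int)


def validate_cells(cells: ad.AnnData) -> ad.AnnData:
    """Check the cell-table invariants; raise :class:`ValidationError` on failure."""
    X = cells.X
    data = X.data if sp.issparse(X) else np.asarray(X).ravel()
    if data.size and data.min() < 0:
        raise ValidationError("negative counts")
    if data.size and np.any(data != np.floor(data)):
        raise ValidationError("non-integer counts")
    for col in ("sample_id", "x", "y"):
        if col not in cells.obs:
            raise SchemaError(f"missing obs column {col!r}")
    xy = cells.obs[["x", "y"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(xy)):
        raise ValidationError("non-finite coordinates")
    nf = np.asarray((X > 0).sum(axis=1)).ravel()
    tc = np.asarray(X.sum(axis=1)).ravel()
    if "n_features" in cells.obs and not np.array_equal(cells.obs["n_features"].to_numpy(), nf):
        raise ValidationError("n_features inconsistent with counts")
    if "total_counts" in cells.obs and not np.array_equal(cells.obs["total_counts"].to_numpy(), tc):
        raise ValidationError("total_counts inconsistent with counts")
    if "cell_type" in cells.obs:
        bad = set(cells.obs["cell_type"].astype(str)) - set(CELL_TYPES)
        if bad:
            raise ValidationError(f"unknown cell types: {sorted(bad)}")
    if "fibro_subtype" in cells.obs:
        bad = set(cells.obs["fibro_subtype"].astype(str)) - set(FIBRO_SUBTYPES)
        if bad:
            raise ValidationError(f"unknown fibroblast subtypes: {sorted(bad)}")
        if "cell_type" in cells.obs:
            off = (cells.obs["fibro_subtype"].astype(str) != "none") & (
                cells.obs["cell_type"].astype(str) != "fibroblast"
            )
            if off.any():
                raise ValidationError("fibro_subtype set on non-fibroblast cells")
    return cells


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".parquet":
        return pd.read_parquet(path)
    return pd.read_csv(path)


def _write_table(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".parquet":
        df.to_parquet(path, index=False)
    else:
        df.to_csv(path, index=False)


def read_cells(path: str | Path, panel: GenePanel) -> ad.AnnData:
    """Read a cell table (wide gene columns, or long cell/gene/count rows).

    Wide layout: one row per cell, columns ``cell_id``, ``x_centroid``/``x``,
    ``y_centroid``/``y``, optional ``sample_id``, plus one column per panel
    gene. Long layout: columns ``cell_id``, coordinates, ``gene`` (or
    ``feature_name``) and ``count``.
    """
    df = _read_table(path).rename(columns={**CELL_COLUMN_MAP, **TRANSCRIPT_COLUMN_MAP})
    if "cell_id" not in df.columns:
        raise SchemaError("cell table requires a cell_id column")
    for col in ("x", "y"):
        if col not in df.columns:
            raise SchemaError(f"cell table requires an {col}(_centroid) column")
    if "sample_id" not in df.columns:
        df["sample_id"] = Path(path).stem
    long_format = "gene" in df.columns and "count" in df.columns
    if long_format:
        unknown = set(df["gene"]) - set(panel.genes)
        if unknown:
            raise ValidationError(f"genes not on panel: {sorted(unknown)[:5]}")
        per_cell = df.drop_duplicates("cell_id").set_index("cell_id")
        counts = (
            df.pivot_table(index="cell_id", columns="gene", values="count",
                           aggfunc="sum", fill_value=0)
            .reindex(index=per_cell.index, columns=list(panel.genes), fill_value=0)
        )
        mat = counts.to_numpy()
        if np.any(mat < 0) or np.any(mat != np.floor(mat)):
            raise ValidationError("counts must be non-negative integers")
        return make_cell_table(
            mat.astype(np.int64), panel.genes, per_cell.index,
            per_cell["sample_id"].to_numpy(), per_cell["x"], per_cell["y"],
        )
    gene_cols = [g for g in panel.genes if g in df.columns]
    meta_cols = set(df.columns) - set(panel.genes)
    unknown = meta_cols - {"cell_id", "sample_id", "x", "y", "cell_type",
                           "fibro_subtype", "niche_id", "niche_type",
                           "n_features", "total_counts"}
    if unknown:
        raise ValidationError(f"unrecognized columns (genes not on panel?): {sorted(unknown)[:5]}")
    if not gene_cols:
        raise SchemaError("no panel gene columns found in wide cell table")
    mat = df[gene_cols].to_numpy()
    if np.any(mat < 0) or np.any(mat != np.floor(mat)):
        raise ValidationError("counts must be non-negative integers")
    full = np.zeros((len(df), len(panel)), dtype=np.int64)
    for j, g in enumerate(panel.genes):
        if g in df.columns:
            full[:, j] = df[g].to_numpy()
    extra = {
        c: df[c].to_numpy()
        for c in ("cell_type", "fibro_subtype", "niche_id", "niche_type")
        if c in df.columns
    }
    return make_cell_table(
        full, panel.genes, df["cell_id"], df["sample_id"].to_numpy(),
        df["x"], df["y"], **extra,
    )


def write_cells(cells: ad.AnnData, path: str | Path) -> None:
    """Write a cell table in the wide platform-style layout."""
    df = pd.DataFrame(
        np.asarray(cells.X.todense() if sp.issparse(cells.X) else cells.X, dtype=np.int64),
        columns=list(cells.var_names),
    )
    df.insert(0, "cell_id", cells.obs_names.to_numpy())
    df.insert(1, "sample_id", cells.obs["sample_id"].to_numpy())
    df.insert(2, "x_centroid", cells.obs["x"].to_numpy())
    df.insert(3, "y_centroid", cells.obs["y"].to_numpy())
    for col in ("cell_type", "fibro_subtype", "niche_id", "niche_type"):
        if col in cells.obs:
            df[col] = cells.obs[col].to_numpy()
    _write_table(df, path)


# ---------------------------------------------------------------------------
# transcript tables


def make_transcript_table(gene, x, y, sample_id) -> pd.DataFrame:
    df = pd.DataFrame({
        "gene": np.asarray(gene, dtype=object),
        "x": np.asarray(x, dtype=float),
        "y": np.asarray(y, dtype=float),
    })
    df["sample_id"] = np.broadcast_to(np.asarray(sample_id, dtype=object), (len(df),))
    return df


def validate_transcripts(tx: pd.DataFrame, panel: GenePanel | None = None) -> pd.DataFrame:
    for col in ("gene", "x", "y", "sample_id"):
        if col not in tx.columns:
            raise SchemaError(f"transcript table requires a {col} column")
    if not np.all(np.isfinite(tx[["x", "y"]].to_numpy(dtype=float))):
        raise ValidationError("non-finite transcript coordinates")
    if panel is not None:
        unknown = set(tx["gene"]) - set(panel.genes)
        if unknown:
            raise ValidationError(f"genes not on panel: {sorted(unknown)[:5]}")
    return tx


def read_transcripts(path: str | Path, panel: GenePanel) -> pd.DataFrame:
    df = _read_table(path).rename(columns=TRANSCRIPT_COLUMN_MAP)
    if "sample_id" not in df.columns:
        df["sample_id"] = Path(path).stem
    return validate_transcripts(df[["gene", "x", "y", "sample_id"]].copy(), panel)


def write_transcripts(tx: pd.DataFrame, path: str | Path) -> None:
    out = tx.rename(columns={v: k for k, v in TRANSCRIPT_COLUMN_MAP.items()})
    _write_table(out, path)


# ---------------------------------------------------------------------------
# metadata and signatures


def validate_sample_meta(meta: pd.DataFrame) -> pd.DataFrame:
    """Per-sample clinical metadata: patient, timepoint, treatment, remission."""
    required = {"sample_id", "patient_id", "timepoint", "treatment", "remission"}
    missing = required - set(meta.columns)
    if missing:
        raise SchemaError(f"sample metadata missing columns: {sorted(missing)}")
    bad_tp = set(meta["timepoint"]) - {"pre", "post"}
    if bad_tp:
        raise ValidationError(f"timepoint must be pre/post, got {sorted(bad_tp)}")
    if meta.duplicated(["patient_id", "timepoint"]).any():
        raise ValidationError("(patient_id, timepoint) pairs must be unique")
    return meta


def load_signature(path: str | Path, name: str | None = None, rmax: int = 1500) -> Signature:
    """Load a signature from a plain-text file, one gene symbol per line."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    genes = [ln for ln in lines if ln and not ln.startswith("#")]
    if not genes:
        raise ValidationError(f"signature file {path} is empty")
    if len(set(genes)) != len(genes):
        dupes = sorted({g for g in genes if genes.count(g) > 1})
        raise ValidationError(f"duplicate genes in signature file: {dupes}")
    return Signature(name=name or Path(path).stem, genes=tuple(genes), rmax=rmax)


def gene_vector(cells: ad.AnnData, gene: str, layer: str | None = None) -> np.ndarray:
    """Dense per-cell vector of one gene (counts or a named layer)."""
    if gene not in cells.var_names:
        raise KeyError(f"gene {gene!r} not on panel")
    j = cells.var_names.get_loc(gene)
    M = cells.layers[layer] if layer else cells.X
    col = M[:, j]
    return np.asarray(col.todense()).ravel() if sp.issparse(col) else np.asarray(col).ravel()
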