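"""Synthetic Xenium-like tissue, cohort and co-culture generator with ground truth.

The generator emulates the geometry of an inflamed synovial biopsy:

* **vessels** — endothelial cores (disk of radius ``r_ec``) wrapped in a mural
  ring, placed on a jittered grid through the sublining;
* **fibroblast field** — a homogeneous Poisson field of sublining fibroblasts
  carrying planted subtypes (fibrogenic, inflammatory, vascular, L1CAM, lowRNA);
* **immune aggregates** — dense disks of T/B/myeloid cells or plasma cells;
* **lining band** — a strip along the top edge mixing lining fibroblasts and
  lining macrophages (split into fibroblast- and macrophage-dominant halves);
* **stromal-adipose corner** — adipocytes with sparse fibroblasts.

Expression is Poisson (optionally negative-binomial) around a per-cell rate
``lambda_g`` built from cell-type/subtype marker rates plus, for fibroblasts,
a distance-to-nearest-endothelial-cell gradient::

    proximal:  lambda_g(d) = a_g * exp(-d / tau_g) + b_g
    distal:    lambda_g(d) = a_g * (1 - exp(-d / tau_g)) + b_g
    flat:      lambda_g(d) = b_g

Transcript points are the parent cell centroid plus isotropic Gaussian jitter,
one point per count, so point totals exactly conserve counts. Everything is
driven by one :class:`numpy.random.Generator`; identical config + seed gives
bit-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .io import ConfigError, GenePanel, make_cell_table, make_transcript_table

__all__ = [
    "GeneModel",
    "SimConfig",
    "SimTruth",
    "SimSample",
    "Cohort",
    "DEFAULT_PANEL",
    "default_gene_models",
    "generate_tissue",
    "generate_coculture",
    "generate_cohort",
]


@dataclass(frozen=True)
class GeneModel:
    """Distance-dependent expression law for one gene in fibroblasts."""

    a: float          # amplitude (counts per cell)
    b: float          # baseline (counts per cell)
    tau: float        # decay length, um
    mode: str         # proximal | distal | flat

    def rate(self, d: np.ndarray) -> np.ndarray:
        if self.mode == "proximal":
            return self.a * np.exp(-d / self.tau) + self.b
        if self.mode == "distal":
            return self.a * (1.0 - np.exp(-d / self.tau)) + self.b
        if self.mode == "flat":
            return np.full_like(np.asarray(d, dtype=float), self.b)
        raise ConfigError(f"unknown gene mode {self.mode!r}")


PANEL_GENES = (
    "PECAM1", "PLVAP", "SELP", "PODXL", "DLL4", "HEY1", "NOTCH4", "NOTCH1",
    "COL4A1", "COL4A2", "ACTA2", "RGS5", "NOTCH3", "PDGFRB", "NOTCH2",
    "COL1A1", "COL3A1", "COL5A1", "COL6A1", "COL6A3", "COL8A1", "COL15A1",
    "COMP", "POSTN", "SPARC", "ASPN", "DKK3", "FMOD", "PRELP", "CXCL12",
    "SFRP1", "THY1", "L1CAM", "CD55", "HTRA1", "CD3E", "MS4A1", "MZB1",
    "ADIPOQ", "TGFB1", "TGFB2", "TGFB3", "TGFBR1", "TGFBR2", "TGFBR3",
    "JAG1", "HES1",
)
DEFAULT_PANEL = GenePanel(PANEL_GENES, panel_kind="custom50")

#: diffuse low-level expression applied to every gene in every cell
#: (cells detect a broad tail of panel genes beyond their markers)
AMBIENT_RATE = 0.2

#: cell-type marker rates (mean counts per cell)
CELL_TYPE_RATES: dict[str, dict[str, float]] = {
    "endothelial": {
        "PECAM1": 6.0, "PLVAP": 1.5, "SELP": 0.8, "PODXL": 0.8, "DLL4": 2.5,
        "HEY1": 2.0, "NOTCH4": 1.5, "NOTCH1": 1.0, "COL4A1": 2.0,
        "COL4A2": 2.0, "JAG1": 1.0, "TGFB1": 1.5, "TGFB3": 1.5,
    },
    "mural": {
        "ACTA2": 6.0, "RGS5": 3.0, "NOTCH3": 3.0, "COL4A1": 1.5,
        "COL4A2": 1.5, "POSTN": 2.0, "TGFB3": 1.5,
    },
    "fibroblast": {
        "PDGFRB": 5.0, "NOTCH2": 4.0, "COL1A1": 4.0, "COL5A1": 3.0,
        "COL3A1": 2.0, "SPARC": 2.0, "COL6A3": 1.0,
    },
    "T": {"CD3E": 6.0},
    "B": {"MS4A1": 6.0},
    "plasma": {"MZB1": 8.0},
    "myeloid": {"HTRA1": 5.0, "TGFB1": 1.5, "TGFB2": 1.5},
    "adipocyte": {"ADIPOQ": 8.0},
}

#: fibroblast-subtype marker rates (added on top of the fibroblast base)
SUBTYPE_RATES: dict[str, dict[str, float]] = {
    "lining": {"CD55": 5.0, "TGFB2": 2.0, "HTRA1": 1.0},
    "fibrogenic": {"COL6A1": 4.0, "COL8A1": 4.0, "ASPN": 2.0, "FMOD": 2.0,
                   "PRELP": 1.5, "DKK3": 1.5},
    "inflammatory": {"CXCL12": 5.0, "SFRP1": 4.0},
    "vascular": {"NOTCH3": 4.0, "THY1": 4.0, "COL15A1": 3.0},
    "L1CAM": {"L1CAM": 5.0},
}

GRADIENT_GENES = ("POSTN", "JAG1", "HES1", "TGFB1", "TGFB3",
                  "COMP", "TGFBR1", "TGFBR2", "TGFBR3", "TGFB2")


def default_gene_models() -> dict[str, GeneModel]:
    """Default endothelial-distance expression laws for fibroblast genes."""
    return {
        "POSTN": GeneModel(6.0, 0.2, 40.0, "proximal"),
        "JAG1": GeneModel(4.0, 0.2, 30.0, "proximal"),
        "HES1": GeneModel(3.0, 0.2, 30.0, "proximal"),
        "TGFB1": GeneModel(2.0, 0.1, 40.0, "proximal"),
        "TGFB3": GeneModel(3.0, 0.1, 40.0, "proximal"),
        "COMP": GeneModel(0.5, 0.05, 60.0, "distal"),
        "TGFBR1": GeneModel(2.0, 0.3, 60.0, "distal"),
        "TGFBR2": GeneModel(3.0, 0.3, 60.0, "distal"),
        "TGFBR3": GeneModel(4.0, 0.2, 60.0, "distal"),
        "TGFB2": GeneModel(1.0, 0.1, 60.0, "distal"),
    }


@dataclass
class SimConfig:
    """All knobs of the tissue/cohort/co-culture generator (lengths in um)."""

    width: float = 2000.0
    height: float = 2000.0
    # vasculature
    n_vessels: int = 12
    r_ec: float = 20.0
    ec_per_core: int = 12
    mural_width: float = 12.0
    mural_per_vessel: int = 14
    vascular_niche_radius: float = 70.0
    # fibroblast field
    fibro_density: float = 1250.0        # cells / mm^2
    subtype_fractions: Mapping[str, float] = field(default_factory=lambda: {
        "fibrogenic": 0.12, "inflammatory": 0.36, "vascular": 0.38,
        "L1CAM": 0.06, "lowRNA": 0.08,
    })
    lowrna_scale: float = 0.12
    fibrogenic_comp_boost: float = 16.0
    # fibrogenic fibroblasts are planted EC-distally (the COMP-high program
    # lives in distal perivascular layers and pauci-cellular regions)
    fibrogenic_min_ec_distance: float = 100.0
    # immune aggregates
    n_aggregates: int = 3
    aggregate_radius: float = 200.0
    aggregate_cells: int = 520
    # lining band / adipose corner
    lining_depth: float = 180.0
    lining_density: float = 900.0        # cells / mm^2
    adipose_size: float = 800.0          # square side, bottom-right corner; 0 disables
    adipose_adipocyte_density: float = 500.0
    adipose_fibro_density: float = 300.0
    # expression model
    gene_models: Mapping[str, GeneModel] = field(default_factory=default_gene_models)
    noise: str = "poisson"               # poisson | nb
    nb_theta: float = 10.0
    jitter_sigma: float = 5.0
    transcript_genes: tuple[str, ...] | None = None   # None -> all panel genes
    # cohort
    n_patients: int = 10
    remission_fraction: float = 0.6
    depletion_factor: float = 0.3
    comp_multiplier: float = 2.0
    comp_density_coupling: float = 0.0
    patient_sigma: float = 0.15
    # co-culture
    knockdown: bool = False
    knockdown_genes: tuple[str, ...] = ("COMP", "TGFBR3")
    knockdown_postn_factor: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("width", "height", "r_ec", "jitter_sigma"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.fibro_density < 0 or self.lining_density < 0:
            raise ConfigError("densities must be non-negative")
        if self.fibro_density == 0 and self.gene_models:
            raise ConfigError("gradient genes requested with zero fibroblast density")
        for g, m in self.gene_models.items():
            if m.tau <= 0:
                raise ConfigError(f"decay length for {g} must be positive")
        if not 0 <= self.remission_fraction <= 1:
            raise ConfigError("remission fraction must lie in [0, 1]")
        if self.noise not in ("poisson", "nb"):
            raise ConfigError("noise must be 'poisson' or 'nb'")

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class SimTruth:
    """Ground truth aligned one-to-one with the generated cell table."""

    cells: pd.DataFrame                  # index = cell_id
    gene_models: Mapping[str, GeneModel]
    vessel_centers: np.ndarray           # (n_vessels, 2)
    config: SimConfig
    expected_comp_positive: float = float("nan")   # expected %COMP+ fibroblasts


class SimSample(NamedTuple):
    cells: ad.AnnData
    transcripts: pd.DataFrame
    truth: SimTruth


@dataclass
class Cohort:
    samples: dict[str, SimSample]
    meta: pd.DataFrame                   # one row per sample
    truth: pd.DataFrame                  # one row per patient


# ---------------------------------------------------------------------------
# geometry helpers


def _vessel_centers(cfg: SimConfig, rng: np.random.Generator,
                    forbidden: list[tuple[float, float, float]],
                    y_min: float) -> np.ndarray:
    """Jittered grid of vessel centers avoiding aggregates/adipose/lining."""
    if cfg.n_vessels <= 0:
        return np.empty((0, 2))
    n_col = int(np.ceil(np.sqrt(cfg.n_vessels)))
    n_row = int(np.ceil(cfg.n_vessels / n_col))
    margin = 60.0
    xs = np.linspace(margin, cfg.width - margin, n_col)
    ys = np.linspace(y_min + margin, cfg.height - margin, n_row)
    grid = np.array([(x, y) for y in ys for x in xs])[: cfg.n_vessels]
    grid = grid + rng.normal(0.0, 25.0, size=grid.shape)
    grid[:, 0] = np.clip(grid[:, 0], 30.0, cfg.width - 30.0)
    grid[:, 1] = np.clip(grid[:, 1], y_min + 30.0, cfg.height - 30.0)
    keep = np.ones(len(grid), dtype=bool)
    for cx, cy, r in forbidden:
        keep &= np.hypot(grid[:, 0] - cx, grid[:, 1] - cy) > r
    if cfg.adipose_size > 0:
        in_adipose = (grid[:, 0] > cfg.width - cfg.adipose_size) & (
            grid[:, 1] > cfg.height - cfg.adipose_size
        )
        keep &= ~in_adipose
    return grid[keep]


def _disk_points(rng: np.random.Generator, center, r_lo, r_hi, n) -> np.ndarray:
    theta = rng.uniform(0, 2 * np.pi, n)
    rr = np.sqrt(rng.uniform((r_lo / max(r_hi, 1e-12)) ** 2, 1.0, n)) * r_hi
    return np.column_stack([center[0] + rr * np.cos(theta),
                            center[1] + rr * np.sin(theta)])


def _aggregate_centers(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    centers: list[tuple[float, float]] = []
    r = cfg.aggregate_radius
    attempts = 0
    while len(centers) < cfg.n_aggregates and attempts < 5000:
        attempts += 1
        x = rng.uniform(r + 30, cfg.width - r - 30)
        y = rng.uniform(cfg.lining_depth + r + 30, cfg.height - r - 30)
        if cfg.adipose_size > 0 and x > cfg.width - cfg.adipose_size - r and (
            y > cfg.height - cfg.adipose_size - r
        ):
            continue
        if any(np.hypot(x - cx, y - cy) < 2 * r + 80 for cx, cy in centers):
            continue
        centers.append((x, y))
    return np.asarray(centers).reshape(-1, 2)


# ---------------------------------------------------------------------------
# expression model


def _rate_matrix(cfg: SimConfig, panel: GenePanel, types: np.ndarray,
                 subtypes: np.ndarray, d_ec: np.ndarray) -> np.ndarray:
    n = len(types)
    gidx = {g: j for j, g in enumerate(panel.genes)}
    lam = np.full((n, len(panel)), AMBIENT_RATE)
    for ctype, rates in CELL_TYPE_RATES.items():
        mask = types == ctype
        if not mask.any():
            continue
        for g, r in rates.items():
            if g in gidx:
                lam[mask, gidx[g]] += r
    fib = types == "fibroblast"
    for stype, rates in SUBTYPE_RATES.items():
        mask = fib & (subtypes == stype)
        if not mask.any():
            continue
        for g, r in rates.items():
            if g in gidx:
                lam[mask, gidx[g]] += r
    for g, model in cfg.gene_models.items():
        if g in gidx and fib.any():
            lam[fib, gidx[g]] += model.rate(d_ec[fib])
    if "COMP" in gidx and cfg.fibrogenic_comp_boost != 1.0:
        boost = fib & (subtypes == "fibrogenic")
        lam[boost, gidx["COMP"]] *= cfg.fibrogenic_comp_boost
    lowrna = fib & (subtypes == "lowRNA")
    lam[lowrna] *= cfg.lowrna_scale
    return lam


def _draw_counts(cfg: SimConfig, rng: np.random.Generator, lam: np.ndarray) -> np.ndarray:
    if cfg.noise == "poisson":
        return rng.poisson(lam)
    # negative binomial as gamma-Poisson mixture with dispersion theta
    shape = cfg.nb_theta
    mix = rng.gamma(shape, lam / shape)
    return rng.poisson(mix)


def _transcripts(cfg: SimConfig, rng: np.random.Generator, panel: GenePanel,
                 counts: np.ndarray, xy: np.ndarray, sample_id: str) -> pd.DataFrame:
    genes = cfg.transcript_genes if cfg.transcript_genes is not None else panel.genes
    parts = []
    for g in genes:
        j = panel.index(g)
        c = counts[:, j]
        total = int(c.sum())
        if total == 0:
            continue
        pts = np.repeat(xy, c, axis=0) + rng.normal(0.0, cfg.jitter_sigma, (total, 2))
        parts.append(pd.DataFrame({"gene": g, "x": pts[:, 0], "y": pts[:, 1]}))
    if not parts:
        return make_transcript_table([], [], [], sample_id)
    tx = pd.concat(parts, ignore_index=True)
    tx["sample_id"] = sample_id
    return tx


# ---------------------------------------------------------------------------
# generators


def generate_tissue(cfg: SimConfig, sample_id: str = "sim",
                    panel: GenePanel = DEFAULT_PANEL) -> SimSample:
    """Generate one synovial-tissue-like sample with ground truth."""
    rng = np.random.default_rng(cfg.seed)
    mm2 = 1e-6  # um^2 -> mm^2

    xs: list[np.ndarray] = []
    types: list[np.ndarray] = []
    subtypes: list[np.ndarray] = []
    niches: list[np.ndarray] = []

    def emit(xy, tp, st, nc):
        xs.append(np.asarray(xy, dtype=float).reshape(-1, 2))
        k = len(xs[-1])
        types.append(np.asarray(tp if not np.isscalar(tp) else [tp] * k, dtype=object))
        subtypes.append(np.asarray(st if not np.isscalar(st) else [st] * k, dtype=object))
        niches.append(np.asarray(nc if not np.isscalar(nc) else [nc] * k, dtype=object))

    # lining band: fibroblast-dominant left half, macrophage-dominant right half
    if cfg.lining_depth > 0 and cfg.lining_density > 0:
        n_lin = rng.poisson(cfg.lining_density * cfg.width * cfg.lining_depth * mm2)
        if n_lin:
            lx = rng.uniform(0, cfg.width, n_lin)
            ly = rng.uniform(0, cfg.lining_depth, n_lin)
            left = lx < cfg.width / 2
            p_fib = np.where(left, 0.7, 0.3)
            is_fib = rng.uniform(size=n_lin) < p_fib
            emit(np.column_stack([lx, ly]),
                 np.where(is_fib, "fibroblast", "myeloid"),
                 np.where(is_fib, "lining", "none"),
                 np.where(left, "liningF", "liningM"))

    # stromal-adipose corner
    if cfg.adipose_size > 0:
        a_area = cfg.adipose_size ** 2 * mm2
        x0, y0 = cfg.width - cfg.adipose_size, cfg.height - cfg.adipose_size
        n_ad = rng.poisson(cfg.adipose_adipocyte_density * a_area)
        if n_ad:
            pts = np.column_stack([rng.uniform(x0, cfg.width, n_ad),
                                   rng.uniform(y0, cfg.height, n_ad)])
            emit(pts, "adipocyte", "none", "stromal-adipose")
        n_af = rng.poisson(cfg.adipose_fibro_density * a_area)
        if n_af:
            pts = np.column_stack([rng.uniform(x0, cfg.width, n_af),
                                   rng.uniform(y0, cfg.height, n_af)])
            st = rng.choice(list(cfg.subtype_fractions), n_af,
                            p=list(cfg.subtype_fractions.values()))
            emit(pts, "fibroblast", st, "stromal-adipose")

    # immune aggregates; alternate T/B- and plasma-dominant
    agg_centers = (_aggregate_centers(cfg, rng) if cfg.n_aggregates > 0
                   else np.empty((0, 2)))
    agg_comps = {
        "immuneT": (["T", "B", "myeloid"], [0.5, 0.3, 0.2]),
        "immuneP": (["plasma", "B", "myeloid"], [0.7, 0.1, 0.2]),
    }
    for i, c in enumerate(agg_centers):
        kind = "immuneP" if i % 3 == 1 else "immuneT"
        ctypes, probs = agg_comps[kind]
        n_agg = cfg.aggregate_cells
        pts = _disk_points(rng, c, 0.0, cfg.aggregate_radius, n_agg)
        emit(pts, rng.choice(ctypes, n_agg, p=probs), "none", kind)

    # vessels
    forbidden = [(cx, cy, cfg.aggregate_radius + 40.0) for cx, cy in agg_centers]
    vessels = _vessel_centers(cfg, rng, forbidden, y_min=cfg.lining_depth)
    for c in vessels:
        emit(_disk_points(rng, c, 0.0, cfg.r_ec, cfg.ec_per_core),
             "endothelial", "none", "vascular")
        emit(_disk_points(rng, c, cfg.r_ec, cfg.r_ec + cfg.mural_width,
                          cfg.mural_per_vessel),
             "mural", "none", "vascular")

    # sublining fibroblast field: homogeneous Poisson thinned to the free region
    if cfg.fibro_density > 0:
        n_cand = rng.poisson(cfg.fibro_density * cfg.width * cfg.height * mm2)
        cand = np.column_stack([rng.uniform(0, cfg.width, n_cand),
                                rng.uniform(0, cfg.height, n_cand)])
        keep = cand[:, 1] > cfg.lining_depth
        if cfg.adipose_size > 0:
            keep &= ~((cand[:, 0] > cfg.width - cfg.adipose_size)
                      & (cand[:, 1] > cfg.height - cfg.adipose_size))
        for cx, cy in agg_centers:
            keep &= np.hypot(cand[:, 0] - cx, cand[:, 1] - cy) > cfg.aggregate_radius
        for cx, cy in vessels:
            keep &= np.hypot(cand[:, 0] - cx, cand[:, 1] - cy) > cfg.r_ec + cfg.mural_width
        pts = cand[keep]
        if len(pts):
            st = rng.choice(list(cfg.subtype_fractions), len(pts),
                            p=list(cfg.subtype_fractions.values()))
            near_vessel = np.full(len(pts), False)
            if len(vessels):
                dv = cKDTree(vessels).query(pts)[0]
                near_vessel = dv <= cfg.vascular_niche_radius
                # the fibrogenic program is EC-distal; proximal cells that
                # drew it become vascular fibroblasts instead
                proximal = dv <= cfg.fibrogenic_min_ec_distance
                st = np.where(proximal & (st == "fibrogenic"), "vascular", st)
            emit(pts, "fibroblast", st,
                 np.where(near_vessel, "vascular", "fibroblast-rich"))

    xy = np.vstack(xs) if xs else np.empty((0, 2))
    tp = np.concatenate(types) if types else np.empty(0, dtype=object)
    st = np.concatenate(subtypes) if subtypes else np.empty(0, dtype=object)
    nc = np.concatenate(niches) if niches else np.empty(0, dtype=object)

    # distance to nearest endothelial cell
    ec_xy = xy[tp == "endothelial"]
    d_ec = (cKDTree(ec_xy).query(xy)[0] if len(ec_xy)
            else np.full(len(xy), np.inf))

    lam = _rate_matrix(cfg, panel, tp, st, d_ec)
    counts = _draw_counts(cfg, rng, lam)

    cell_ids = [f"{sample_id}_{i:05d}" for i in range(len(xy))]
    cells = make_cell_table(counts, panel.genes, cell_ids, sample_id,
                            xy[:, 0], xy[:, 1])
    tx = _transcripts(cfg, rng, panel, counts, xy, sample_id)

    truth_cells = pd.DataFrame({
        "true_cell_type": tp, "true_subtype": st, "true_niche": nc,
        "dist_ec": d_ec,
    }, index=pd.Index(cell_ids, name="cell_id"))
    exp_comp = float("nan")
    for g in ("COMP", "POSTN"):
        if g in panel.genes:
            lam_g = lam[:, panel.index(g)]
            truth_cells[f"lambda_{g}"] = lam_g
            fib = tp == "fibroblast"
            hi = np.zeros(len(xy), dtype=bool)
            if fib.any():
                thr = np.quantile(lam_g[fib], 0.9)
                hi[fib] = lam_g[fib] > thr
            truth_cells[f"{g}_hi"] = hi
    fib = tp == "fibroblast"
    if "COMP" in panel.genes and fib.any():
        exp_comp = 100.0 * float(np.mean(1.0 - np.exp(-lam[fib, panel.index("COMP")])))
    truth = SimTruth(truth_cells, dict(cfg.gene_models), vessels, cfg, exp_comp)
    return SimSample(cells, tx, truth)


def generate_coculture(cfg: SimConfig, sample_id: str = "coculture",
                       panel: GenePanel = DEFAULT_PANEL) -> SimSample:
    """EC clusters scattered through a fibroblast monolayer (in-vitro layout).

    In ``knockdown`` mode the de-repressed distal genes (default COMP and
    TGFBR3) switch to a flat profile at their distal plateau, and the POSTN
    amplitude is scaled by ``knockdown_postn_factor`` — mimicking loss of
    endothelial Notch ligand.
    """
    models = dict(cfg.gene_models)
    if cfg.knockdown:
        if not cfg.knockdown_genes:
            raise ConfigError("knockdown mode requires a non-empty affected-gene list")
        for g in cfg.knockdown_genes:
            if g in models:
                m = models[g]
                models[g] = GeneModel(0.0, m.a + m.b, m.tau, "flat")
        if "POSTN" in models:
            m = models["POSTN"]
            models["POSTN"] = GeneModel(m.a * cfg.knockdown_postn_factor,
                                        m.b, m.tau, m.mode)
    flat_cfg = cfg.replace(
        gene_models=models, lining_depth=0.0, adipose_size=0.0, n_aggregates=0,
        mural_per_vessel=0, fibrogenic_comp_boost=1.0,
        subtype_fractions={"inflammatory": 1.0},
    )
    sample = generate_tissue(flat_cfg, sample_id=sample_id, panel=panel)
    sample.truth.cells["condition"] = "knockdown" if cfg.knockdown else "control"
    return sample


def save_sample(sample: SimSample, out_dir, fmt: str = "csv") -> None:
    """Write a simulated sample in the same schema as real inputs, plus the
    ground-truth sidecar (Parquet) and the resolved config (YAML)."""
    from pathlib import Path

    import yaml

    from .io import write_cells, write_transcripts

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_cells(sample.cells, out / f"cells.{fmt}")
    write_transcripts(sample.transcripts, out / f"transcripts.{fmt}")
    sample.truth.cells.to_parquet(out / "truth.parquet")
    cfg = dataclasses.asdict(sample.truth.config)
    cfg["gene_models"] = {g: dataclasses.asdict(m)
                          for g, m in sample.truth.config.gene_models.items()}
    cfg["subtype_fractions"] = dict(cfg["subtype_fractions"])
    (out / "sim_config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=False))


def generate_cohort(cfg: SimConfig, panel: GenePanel = DEFAULT_PANEL) -> Cohort:
    """Paired pre/post samples for ``n_patients`` patients.

    Post-treatment samples have immune aggregates scaled by
    ``depletion_factor`` in every patient. In non-remission patients only, the
    COMP amplitude is multiplied by ``comp_multiplier`` (times patient-level
    log-normal noise); ``comp_density_coupling`` > 0 additionally thins the
    post-treatment fibroblast field by ``multiplier ** -coupling``, modelling
    the drift of expanding COMP-high regions toward pauci-cellularity.
    """
    if cfg.n_patients < 2:
        raise ConfigError("cohort requires at least 2 patients")
    rng = np.random.default_rng(cfg.seed)
    n_rem = int(round(cfg.n_patients * cfg.remission_fraction))
    remission = np.zeros(cfg.n_patients, dtype=bool)
    remission[rng.permutation(cfg.n_patients)[:n_rem]] = True

    samples: dict[str, SimSample] = {}
    meta_rows, truth_rows = [], []
    seeds = np.random.SeedSequence(cfg.seed).generate_state(2 * cfg.n_patients + 1)
    for i in range(cfg.n_patients):
        pid = f"P{i + 1:02d}"
        mult = (cfg.comp_multiplier if not remission[i] else 1.0) * float(
            rng.lognormal(0.0, cfg.patient_sigma))
        das_pre = float(rng.uniform(3.6, 7.0))
        das_post = float(rng.uniform(1.2, 2.5) if remission[i] else rng.uniform(2.8, 6.0))
        treatment = "DMARD" if i % 2 == 0 else "adalimumab"
        models = dict(cfg.gene_models)
        post_models = dict(models)
        if "COMP" in post_models:
            m = post_models["COMP"]
            post_models["COMP"] = GeneModel(m.a * mult, m.b * mult, m.tau, m.mode)
        configs = {
            "pre": cfg.replace(seed=int(seeds[2 * i] % 2**31), gene_models=models),
            "post": cfg.replace(
                seed=int(seeds[2 * i + 1] % 2**31),
                gene_models=post_models,
                aggregate_cells=max(0, int(round(cfg.aggregate_cells * cfg.depletion_factor))),
                fibro_density=cfg.fibro_density * mult ** (-cfg.comp_density_coupling),
            ),
        }
        pair = {}
        for tp, c in configs.items():
            sid = f"{pid}_{tp}"
            samples[sid] = generate_tissue(c, sample_id=sid, panel=panel)
            pair[tp] = samples[sid]
            meta_rows.append({
                "sample_id": sid, "patient_id": pid, "timepoint": tp,
                "treatment": treatment,
                "remission": "yes" if remission[i] else "no",
                "das28_baseline": das_pre, "das28_delta": das_post - das_pre,
            })
        truth_rows.append({
            "patient_id": pid, "remission": bool(remission[i]),
            "comp_multiplier": mult,
            "true_comp_positive_pre": pair["pre"].truth.expected_comp_positive,
            "true_comp_positive_post": pair["post"].truth.expected_comp_positive,
            "true_delta_comp": pair["post"].truth.expected_comp_positive
            - pair["pre"].truth.expected_comp_positive,
        })
    meta = pd.DataFrame(meta_rows)
    return Cohort(samples, meta, pd.DataFrame(truth_rows))
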