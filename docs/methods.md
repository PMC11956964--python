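# Methods

`synospace` re-implements, as a tested pipeline, a spatial-transcriptomics
analysis of inflamed synovium: niche segmentation and scoring, transcript
kernel-density colocalization, endothelial-distance expression gradients,
mutually exclusive high-expresser gating, and paired pre/post-treatment
metrics. Because suitable public imaging-based datasets of this design are
not available, every stage is validated against a synthetic tissue generator
with known ground truth. This note records the models, the defaults and why,
and what the synthetic validation does and does not establish.

## Data model and conventions

Cells live in an `AnnData`: sparse integer counts over a gene panel, per-cell
metadata (sample, centroid `x`/`y`) and derived analysis labels. Coordinates
are micrometres in the imaging convention — origin top-left, y increasing
downward; all distances are Euclidean in µm. Transcript detections are plain
tables of (gene, x, y, sample). On-disk formats are the platform-style CSV /
Parquet exports (`cell_id`, `x_centroid`, `y_centroid`, `feature_name`,
`x_location`, `y_location`), mapped to internal names on read.

## Preprocessing

**QC.** Cells detecting `min_features` or fewer gene species are removed
(default 50, matching the discovery-panel convention; on a ~50-gene targeted
panel a threshold of ~5 is appropriate and is what the demo uses).

**Normalization** follows the median-scale-factor rule: for a cell with
total count *t* in a sample with median total *m*, a count *c* maps to
`log(1 + c·m/t)`. Note a subtlety: this rule is invariant to rescaling one
cell's depth, but *not* to a global rescaling of all counts (the median
rescales too). On small targeted panels it also couples genes
compositionally — a cell's normalized value for one gene depends on every
other gene through *t*. Rank-based scores are immune to this; correlation
analyses on few-gene panels are not, and raw-count options are provided
where it matters.

**Cell typing** is rule-based rather than cluster-then-annotate: each type
has a marker set (score = mean normalized marker expression) and optional
required-positive genes (e.g. fibroblasts require `PDGFRB > 0` and
`NOTCH2 > 0` counts). The best-scoring eligible rule wins; ties break by
rule order. A confidence floor (`type_min_score`, default 0.8 on the log
scale) sends cells whose best score rests on a stray single count to
`other` — without it, ambient single-molecule detections mint spurious rare
cells (a single false "endothelial" cell corrupts every distance-to-EC
computation downstream, which is why the floor is on by default in the
pipeline). Fibroblast subtyping works the same way over subtype marker sets
(lining, fibrogenic, inflammatory, vascular, L1CAM), with fibroblasts below
a detection floor labelled `lowRNA`.

**Niche segmentation** deliberately replaces embedding-based niche tooling
with a transparent two-step procedure:

1. *Patches*: k-means on cell coordinates with n/k centres (default k = 15
   cells per patch) yields compact, spatially contiguous patches that adapt
   to local density. We initially used greedy nearest-neighbour agglomeration
   and patch size 30; greedy growth leaves ragged leftover patches straddling
   niche boundaries, and 30-cell patches cannot resolve perivascular annuli
   a few cell layers thick even with oracle labels, so compact 15-cell
   patches are the default.
2. *Clustering and naming*: patch cell-type composition vectors (with
   fibroblasts split into lining/sublining) are Leiden-clustered on a kNN
   graph with Gaussian similarity edge weights at a local scale — the
   weighting prevents small but distinct patch groups (a handful of lining
   patches) from being absorbed by the nearest large cluster. Clusters are
   named against a label dictionary of seven niche archetypes
   (fibroblast-rich, vascular, stromal-adipose, liningF, liningM, immuneT,
   immuneP) by weighted composition score; several clusters may share a name.

Niche *tissue area* is the sum of patch convex-hull areas (degenerate patches
fall back to a per-cell area constant, default 100 µm²); per-sample area
fractions feed Ward hierarchical clustering of samples and niche-area
correlations (two-sided Pearson).

## Signature scoring

Per-cell scores use the capped-rank (UCell-style) statistic: rank all panel
genes within the cell by decreasing expression (average ranks on ties), cap
ranks at `rmax + 1`, and with `n` signature genes on the panel set
`U' = Σ ranks − n(n+1)/2`, `score = max(0, 1 − U'/(n·rmax))`. The effective
`rmax` is clamped to the panel size: with the conventional default of 1500
on a ~50-gene panel the raw formula would collapse all scores to ~1.
Scores depend on expression only through within-cell ranks, hence are
invariant to any monotone per-cell transform and to the normalization
choice. Niche scores are the mean of cell scores over the niche's cells
(whether the original analysis used cell means or niche pseudobulk is not
stated; cell means are simpler and transform-stable). Niche-type contrasts
follow the down-sampling convention — 500 niches drawn from the focal type
vs 500 from the rest (with replacement below 500, logged), two-sided
Mann-Whitney U, Bonferroni across types.

## KDE, highest-density regions, colocalization

Transcript fields are Gaussian product-kernel KDEs evaluated by linear
binning plus Gaussian convolution (numerically the direct sum at grid
resolution, O(grid) cost). Defaults: 10 µm pixels (5 µm in fine-grid
checks), per-axis normal-scale bandwidth `h = σ·n^{−1/6}`, grids padded by
four bandwidths so the field integrates to 1 ± 10⁻³ over the plane. A full
2-D plug-in bandwidth selector was considered and rejected: for the
near-Gaussian clouds where it is well characterized it reduces to the
normal-scale rule, and the bandwidth is user-settable everywhere.

"50 % contour" regions are highest-density regions: pixels are accumulated
in decreasing density order until the requested probability mass is reached,
so masks at increasing mass levels nest exactly and the realized mass
overshoots by at most one pixel. A fraction-of-peak threshold convention is
available as an alternative (`threshold_mask`).

Pixel-wise colocalization is the Pearson correlation of two genes' density
values over the pixels of a mask, computed per sample and averaged across
samples (samples, not pooled pixels, are the unit). Two caveats are built
into the defaults: correlations are only taken within a tissue mask (the
empty padding ring correlates any two fields through the shared support),
and the colocalization bandwidth is fixed at 30 µm — roughly the
cell-neighbourhood scale — because sample-size-driven bandwidths (~80 µm at
n = 2000 points) over-smooth local structure and inflate correlations
between unrelated genes (null mean |R| ≈ 0.25 vs ≈ 0.05 at 30 µm). Since
images are not ingested, "stain above background" masking is proxied by
cell-centroid density above a quantile threshold. COMP-high-region cell
density is the count of cell centroids inside the 50 % HDR of the COMP
transcript KDE divided by the mask area, in cells/mm².

## Endothelial-distance gradients

Each cell's distance to the nearest endothelial-typed cell (centroids; no
boundaries exist in the tabular model) is computed with a k-d tree;
reference cells get distance 0. Expression is profiled in half-open 23 µm
bins — roughly one cell layer — reporting mean, population sd (the ribbon is
one sd, not a standard error) and n per bin; bins under 10 cells are
flagged. Profile monotonicity is summarized by the Spearman ρ of bin means
vs bin centres; in recovery tests the profile is evaluated over 0–3τ of the
planted law, because beyond ~3τ the law is flat by construction and plateau
bins contribute only rank noise. The top-vs-bottom quantile test compares
nearest-EC distances of the top and bottom expression quantiles among
expressing cells (default quartiles, ties at the boundary join the top
group) with a two-sided Mann-Whitney U (exact below 9 per group without
ties, tie-corrected normal approximation otherwise — the convention used for
every U test in the package).

## Gating and longitudinal metrics

COMP/POSTN gating mimics the co-culture convention: among cells expressing a
gene (raw count > 0), the top-q quantile defines candidates (default top
25 %); an exclusivity cap (default `POSTN ≤ 3.5` counts for COMP-high)
removes double positives, and residual double-qualifiers are dropped from
both gates. Gating operates on raw counts because the printed cap is on a
counts scale; a normalized-layer switch exists. %COMP⁺ fibroblasts is
`100 × |count > 0| / |fibroblasts|` on raw counts — invariant to
normalization settings by construction.

Longitudinal records pair pre/post samples per patient: Δ%COMP⁺ =
post − pre, "stable" means |Δ| < 1 percentage point, and the Δ-vs-density
correlation pairs Δ%COMP⁺ with the *post*-treatment COMP-high-region cell
density (the phrasing of the original observation is ambiguous between post
density and Δdensity; post is the default, Δ an option). Immune abundance
change reports per-patient pre/post proportions of T, B, plasma and myeloid
cells among all cells.

## The synthetic tissue generator

The generator emulates an inflamed synovial biopsy on a 2 × 2 mm domain:
jittered-grid vessels (endothelial cores r = 20 µm with 12 EC, mural rings
12 µm wide with 14 cells), a homogeneous-Poisson sublining fibroblast field
(1250 cells/mm²), three dense immune aggregates (r = 200 µm, 520 cells;
T/B-dominant or plasma-dominant), a 180 µm lining band split into
fibroblast- and macrophage-dominant halves, and an adipocyte-rich corner
(800 µm square). Structure sizes were chosen to be realistic for synovium
(aggregates and lining bands are hundreds of µm). Counts are Poisson
(negative binomial optional, dispersion θ) around per-cell rates built from
cell-type and subtype marker rates, a diffuse 0.2-count ambient floor over
the whole ~47-gene panel (so single-marker cell types detect a realistic
~10 gene species), and, in fibroblasts, distance-to-nearest-EC laws:
proximal `a·e^{−d/τ} + b`, distal `a·(1 − e^{−d/τ}) + b`, flat `b`.
Defaults: Notch targets and POSTN proximal (τ = 30–40 µm), COMP and the
TGF-β receptors distal (τ = 60 µm). Field fibroblasts carry planted subtypes
(fibrogenic 12 %, inflammatory 36 %, vascular 38 %, L1CAM 6 %, lowRNA 8 %
with all rates scaled ×0.12). The fibrogenic subtype multiplies the COMP
rate ×16 and is planted only at EC distance > 100 µm — the COMP-high program
is EC-distal — which also makes the planted "COMP-high" truth (top decile of
true λ_COMP among fibroblasts) an identifiable target: without the spatial
restriction the decile boundary slices a continuum of near-identical rates
that no method could recover from Poisson counts. Transcript points are the
parent centroid plus isotropic Gaussian jitter (σ = 5 µm, small against the
23 µm bin width), one point per count, so point totals conserve counts
exactly.

Cohorts draw paired pre/post samples per patient: post samples scale immune
aggregate size by the depletion factor (default 0.3) in everyone, and
multiply the COMP amplitude (×2 by default, with log-normal patient noise,
σ = 0.15) only in non-remission patients. A coupling exponent optionally
thins the post-treatment fibroblast field by `multiplier^{−coupling}`,
modelling the drift of expanding COMP-high regions toward pauci-cellularity;
the null configuration (multiplier 1, coupling 0) leaves pre and post
generative parameters identical up to patient noise. Co-culture mode strips
tissue structure (EC clusters in a fibroblast monolayer); ligand-knockdown
mode switches the de-repressed distal genes (COMP, TGFBR3) to a flat profile
at their distal plateau and scales the POSTN amplitude down. Co-culture
validation uses the stronger in-vitro amplitudes (COMP a = 5, b = 0.1,
τ = 50 µm) reflecting the higher per-cell detection of targeted in-vitro
assays.

Everything is driven by one `numpy` generator per call; identical config and
seed give bit-identical tables.

**What the generator does not model**: segmentation errors, doublets,
optical crowding, spatially correlated noise, batch effects across samples,
or the real dispersion of imaging-based counts (Poisson by default — chosen
to keep recovery tests analytic). Passing recovery tests therefore
demonstrates correctness of the *algorithms* under a clean generative model,
not performance on real tissue; with real data the marker dictionaries,
QC thresholds, bandwidths and the niche label dictionary all require
dataset-specific configuration.

## Validation scales and numerical choices

The verification suite (and `scripts/acceptance.py`, which recomputes the
same quantities from scratch) uses: 100 random 20-gene × 50-cell matrices
against an explicit sort-and-formula rank oracle (agreement to 10⁻¹²);
10⁵-point Gaussian clouds for KDE mass (±10⁻³) and 50 % HDR area (within 3 %
of π(1.1774σ)², the closed form — normal-scale smoothing alone inflates the
area by ~2 % at this n, which drove the choice of n); 20 independent and 1
planted point-pattern pair for colocalization (null mean |R| < 0.2, planted
R > 0.8); one ~5,500-fibroblast tissue for gradient recovery (|ρ| ≥ 0.9 with
the generative sign, quantile test p < 0.01) plus 500 Poisson-redraw
replicates on fixed geometry for type-I calibration ([0.03, 0.07] at
α = 0.05); 100 random instances ≤ 500 cells against the all-pairs distance
oracle; one default tissue for niche ARI (≥ 0.8) and 15 synthetic samples
for archetype clustering; one default tissue for gate precision/recall
(≥ 0.7 each, with the gate quantile set to `0.1·n_pop/n_expressing` so the
expressing-cell quantile targets the top population decile that defines the
planted truth); and 100 ten-patient cohorts (50 coupled, 50 null; 1.2 mm
domains) for the longitudinal pipeline. Cohort and demo domains are smaller
than the default tissue so that the full suite completes in a few minutes.

## Known limitations

- The niche label dictionary is a fixed weighted-composition scorer; novel
  niche types in real data would need new entries.
- Patch-based segmentation cannot resolve structures thinner than a patch
  (~4 cell diameters at k = 15).
- Median-scale normalization on targeted panels couples genes through the
  per-cell total; correlation-type analyses on few-gene panels should
  consider the raw-count options.
- The quantile gate inherits count discreteness: tie inclusion at the
  threshold makes realized gate sizes jump; thresholds are always reported.
- Exact Mann-Whitney p-values are used only below 9 observations per group
  without ties; elsewhere the tie-corrected normal approximation applies.
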