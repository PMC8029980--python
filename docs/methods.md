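# Methods

This note documents the models and procedures implemented in `histoplex`,
the parameters that matter, the design choices made where the standard
protocol leaves the design open, and what the synthetic-data generators do
and do not emulate.

## Phenotyping

**Normalization.** Marker mean fluorescence intensities (MFIs) are
standardized per marker to z-scores and trimmed to ±5 to suppress outlier
influence. The *population* standard deviation (ddof = 0) is used; the
convention is fixed and documented so that downstream fingerprints are
stable. Zero-spread columns map to all zeros. Normalization can be computed
within each sample/core (`by=` argument) — in cyclic IHC it then doubles as
a batch correction — or pooled; per-core is the pipeline default.

**Consensus annotation.** Three independent clustering runs, each annotated
to phenotype names, vote per cell: a label with ≥ 2 votes wins, full
disagreement yields `other`. The clustering runs are pluggable — any three
per-cell label vectors are accepted. The built-in default runs k-means
three times with distinct seeds on a uniform random subsample of 25,000
cells (sampling scheme: uniform without replacement, seeded), at twice as
many clusters as reference phenotypes — k-means at k equal to the
phenotype count tends to absorb rare populations (e.g. fDC at ~1 % of
cells) into larger clusters, while annotation folds overclustered splits
back together. Cluster ids
are mapped to phenotype names by nearest reference fingerprint, standing in
for the expert annotation step, which is an input to the pipeline rather
than part of it. Community-detection algorithms (PhenoGraph-style) are
deliberately not re-implemented; the consensus logic is the tested
contribution.

**Fingerprint propagation.** A phenotype fingerprint is the mean z-vector
of its consensus-labelled cells (cells labelled `other` are excluded from
fingerprint construction — `other` is a disagreement bucket, not a cell
type). All cells are then labelled by minimum Euclidean distance to the
fingerprints; exact ties break to the lexicographically smallest phenotype
name so the map is deterministic.

**Gating.** Subtype gates operate on asinh-transformed MFI (cofactor 1 by
default, intensities being already normalized). Because the protocol
specifies manual gating without numeric cutoffs, two default threshold
rules are provided: "high" gates (PD-1-high TFH) use the 90th percentile of
the parent population; +/− gates (BCL6, BCL2, HLA-DR) use the midpoint of
the exact two-class 1-D partition (minimum within-class sum of squares,
computed by exhaustive scan over sorted split points — deterministic, no
k-means initialization noise). Both are stand-ins for expert-chosen
cutoffs and are configurable per rule.

## In-silico microdissection

Tissue is rasterized into half-open square tiles of 50 px (default); at
0.45 µm/px a tile is 22.5 µm on a side. Cell (x, y) maps to tile
(⌊x/50⌋, ⌊y/50⌋); image convention throughout (origin top-left, y down,
0-based pixels).

**Tumor mask.** Tiles with ≥ 1 melanoma cell, then a 3 × 3 binary median
filter with zero (background) padding — the minimal kernel that removes
isolated outlier tiles; for binary input it is a 5-of-9 majority vote, so
isolated tiles vanish and the corners of solid blocks are shaved.

**Germinal-center mask.** A tile qualifies when fDC + germinal-center B
cells + B cells make up ≥ 50 % of the cells in the tile (fraction of cells
in that tile; empty tiles never qualify since the fraction is undefined at
zero cells). Connected objects — 8-connectivity by default, configurable —
smaller than 10 tiles are removed, as are objects not containing at least
one cell of each of the three defining phenotypes. The size filter is
idempotent and the mask shrinks monotonically in both the fraction and the
minimum object size.

**Region assignment.** Cells take the region label of their tile. When
masks overlap a precedence order is required (pipeline default:
GC > tumor); cells outside every mask are `unassigned`. Region areas used
for densities are mask areas: n_tiles × (tile_px × µm/px / 1000)².

## Composition statistics

Per (sample, region): counts, percentage of all cells, percentage within
the phenotype's lineage (B, T, NK, dendritic, macrophage, melanoma,
vasculature, epithelial, stroma, other), and density in cells/mm² where an
area is known. Between-group comparisons use the two-sided Wilcoxon
rank-sum test per phenotype and metric: the exact null distribution when
both groups have ≤ 10 samples and no ties, otherwise the normal
approximation with continuity correction. `other`, `Stroma` and `Epith`
are excluded from comparisons. P-values are unadjusted by default
(exploratory, small n); Benjamini–Hochberg adjustment is available behind
a flag.

## Neighborhood analysis

**Statistic.** For ordered pair (A, B): the mean number of B cells whose
center lies within radius r (default 50 px ≈ 22 µm, about one cell
diameter beyond the edge of an average 7-µm-radius cell) of an A cell,
self excluded, Euclidean distance on pixel coordinates, boundary inclusive.
The statistic is asymmetric (per-A-cell mean); counts are computed with a
k-d tree and verified against an O(n²) oracle.

**Constrained permutation null.** Labels of movable cells are permuted
uniformly over their observed positions N times (default 1000); melanoma
phenotypes are held fixed — label and position — because melanoma grows in
large clusters and randomizing it would exaggerate every other pairwise
attraction. `other`/`Stroma`/`Epith` are excluded before analysis. The
attraction p-value uses a pseudo-count, p = (1 + #{perm ≥ obs}) / (N + 1),
so p ∈ (0, 1]; an avoidance p-value (≤ direction) is computed and exported
but not classified. Pairs of two fixed phenotypes have a
permutation-invariant statistic and receive p = 1 by convention. With an
empty fixed set the procedure reduces exactly to the standard
label-permutation test (verified against an independent oracle sharing the
seed).

**Classification and integration.** p < 0.05 → strong, p < 0.1 → moderate,
otherwise none. Cross-sample integration is the weighted average of a
per-pair score with weight w_s = log10(√(n_A,s · n_B,s)) (log10 of the
geometric mean of the two phenotype counts); zero-weight samples are
excluded and a pair with no positive weight is missing. The integrated
score defaults to the attraction p-value — the only per-pair significance
score the protocol defines — but the operation is score-agnostic and the
observed statistic can be integrated instead. Whether permutations should
be pooled across cores of one patient is left to the caller (one analysis
object per region/core; integration merges them).

## Cytokine-panel selection

**LOOCV-LDA.** Each sample is held out once; marker z-scores are fitted on
the training fold only and applied to the held-out sample (leakage-free;
a global-normalization mode exists behind a flag for fidelity comparisons,
since the protocol's order of operations is ambiguous). A two-class LDA
with equal priors — chosen over empirical priors given tiny, imbalanced
cohorts — is fitted on the fold; the pooled covariance is the equal-prior
average of the biased class covariances with a ridge term of 1e-6 on the
diagonal for near-singular fits (panel size approaching fold size). The
discriminant is evaluated in closed form, w = Σ⁻¹(μ₁ − μ₀) with intercept
−½(μ₁ + μ₀)ᵀw, which the test suite verifies fold-by-fold against
scikit-learn's `LinearDiscriminantAnalysis` (lsqr solver, equal priors) to
1e-8. Accuracy is the fraction of correctly predicted held-out samples;
residual probability is Σ(1 − posterior of the true class) over folds —
named but not defined by the protocol, this definition makes it a
continuous tie-breaker that rewards confident correct predictions.

**Search and selection.** All C(M, k) subsets for each k = 1..M are scored
(M = 14 ⇒ 16,383 panels; a cap of 20 markers guards against accidental
exponential blow-ups and can be overridden). Per size the winner maximizes
accuracy, ties break to minimal residual probability, then to the
lexicographically smallest marker tuple, making the search deterministic
and invariant to column order. The optimal size is the elbow of the
per-size best-accuracy front, formalized as the size with maximum
perpendicular distance to the chord joining the first and last front
points; ties — including a perfectly flat or linear front — go to the
smallest size (simplest model). LOOCV accuracy is *not* assumed monotone
in k, and the search does not rely on it.

## Synthetic data

**Tissue.** One call simulates one sample: melanoma nests are hard discs
with uniformly scattered interiors; border phenotypes occupy the annulus
[R, 1.5R] around a nest (interface width R/2); germinal-center blobs are
shared compact discs jointly populated by all blob-mode phenotypes
(round-robin assignment guarantees every blob at least one cell of each
when counts permit, and blob centers are rejection-sampled ≥ 3 blob-radii
apart so blobs are distinct); uniform phenotypes fill the background.
Marker intensities are log-normal around per-phenotype fingerprint means —
MFI data are positive and right-skewed, and no generative model is
prescribed by the protocol — with a common log-scale noise SD (default
0.35). The default sample is 2000 × 2000 px at 0.45 µm/px with 3 nests of
radius 300 px and one GC blob of radius 150 px; the demo configuration
places ~5,000 cells across 11 phenotypes. The generator emulates the
spatial regimes the analyses assume (clustered tumor, border-enriched
infiltrate, compact GC), not raw images: segmentation errors, registration
artifacts, intensity spillover and cell-shape effects are out of scope, so
passing tests demonstrate correctness of the computational stages, not
robustness to upstream imaging noise.

**Cytokines.** Samples × markers Gaussian matrices (default the 14-plex
panel); informative markers receive a mean shift of effect_size × noise_sd
in one group, uninformative markers are identically distributed. With five
informative markers at a standardized shift of 3 and groups of 6, any two
informative markers already separate the groups perfectly in LOOCV
(Mahalanobis distance 3√2 ≈ 4.2), so both accuracy and residual
probability saturate by panel size 2 — under these conditions no front
carries information that would place an elbow at size 5, and the
parameter-recovery simulation reports this honestly rather than adjusting
the conditions.

## Problem sizes and numerical conventions

- Permutation-null calibration uses 200 replicate tissues of 180 cells
  with 199 permutations each; attraction detection uses 100 replicates of
  270 cells. The panel-recovery simulation uses 50 replicates of the full
  16,383-panel search (n = 12 samples each).
- All randomness flows through `numpy.random.default_rng` seeds carried in
  the configuration objects; identical seed and configuration give
  byte-identical outputs, including pipeline artifacts.
- Distances are computed on pixel coordinates; physical units enter only
  through the µm/px resolution metadata (areas, radius annotations).
- Boundary conventions: tiles are half-open, neighbor radii inclusive,
  z-trim inclusive, gate thresholds strict (> threshold is positive).

## Known limitations

- Cluster-to-phenotype annotation quality is an input; the nearest-
  fingerprint stand-in assumes reference fingerprints in the same z-space.
- The manual Pos/NegInPos/NegTum dissection of real studies is not
  algorithmically reproduced; such masks can be supplied externally and
  applied with the same region-assignment machinery.
- Exact Wilcoxon p-values are unavailable under ties (the implementation
  falls back to the corrected normal approximation).
- The neighborhood statistic is a short-range count; long-range or
  density-adjusted interaction kernels are out of scope.
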