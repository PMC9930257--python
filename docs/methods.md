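# Methods

`regulonscape` reconstructs a regulon-activity landscape from single-cell
RNA-seq counts: which transcription-factor programs are on in which cells,
how per-cell gene-gene association networks differ between cell states, and
how cells order along a differentiation trajectory when described by regulon
activity instead of raw expression. This note records the models, the
parameters that matter, and the design choices made where the design was
genuinely open.

## Quality control and normalization

Cells are kept when (i) their detected-gene count lies in
`[min_genes, max_genes]` (defaults 200 / 5000 — the usual droplet bounds for
excluding empty/low-quality droplets and doublets), (ii) their mitochondrial
count fraction (genes with the `MT-` prefix) is at most `max_mito_frac`
(default 0.15), (iii) every required lineage marker (default `RUNX2`, the
early osteoblast master regulator) has a raw count > 0, and (iv) every
excluded contaminant gene (default the hemoglobin genes `HBM`, `HBA1`,
`HBA2`, `HBB`, marking erythroid carry-over) has a raw count of 0. "Expressed"
is interpreted as raw count > 0 throughout; a cell failing several rules is
attributed to the first failing rule in the fixed order (low, high, mito,
marker, hemoglobin) so QC reports are reproducible. Counts are then scaled
to 10,000 molecules per cell and log1p-transformed; per-cell `expm1` sums
reproduce the scale total exactly, which the tests assert.

Highly variable genes are ranked by dispersion (variance/mean) computed on
the normalized-count scale (`expm1` of the log values). Dispersion on the
log scale was tried first and rejected: for sparse data it is maximized by
pure-noise genes whose values alternate between 0 and a large log-normalized
constant, and it ranked every planted marker below the noise floor.
PCA centers and (by default) unit-scales each gene; component signs are
fixed by making each component's largest-magnitude loading positive, and
per-component variance percentages are `stdev^2 / sum(stdev^2) * 100`.
The number of PCs is a parameter (default 18); no automated elbow/jackstraw
selection is performed. A seeded k-means clusterer is provided as a baseline;
externally supplied labels are accepted everywhere labels are consumed.

## Regulon activity (recovery-curve AUC)

A regulon — a TF with its target set — is scored per cell by the area under
the gene-set recovery curve over the top fraction of that cell's
expression-ranked genes. With `G` genes and `T = ceil(top_frac * G)`, the
raw area is `sum_{t=1..T-1} hits(t)`, normalized by the best achievable
`sum_{t=1..T-1} min(t, |S|)`, so scores live in `[0, 1]` and depend on
expression only through the within-cell ranking (hence invariant to any
monotone transform, and robust to dropout of individual genes). Ties —
dominated by the zero block — are broken by a seeded shuffle; the seed is a
recorded parameter, without which the score would be ill-defined on sparse
data. The integration is a left-rectangle sum of the step curve, normalized
by its maximum; variants of this area exist in the literature, so the exact
construction is stated here and frozen by unit tests.

`top_frac` defaults to 0.05, the conventional operating point for
transcriptome-scale data (top ~1000 of 20k genes). On the ~150-gene
synthetic universe that yields only T = 8 usable ranks and a heavily
quantized score, so the pipeline and tests use `top_frac = 0.2` there —
chosen so that T comfortably exceeds the planted set size, which is the
property that matters, not the fraction itself.

Differential activity across clusters uses the Kruskal–Wallis test with tie
correction (activity scores and sparse expression are far from normal) with
Benjamini–Hochberg adjustment across features within a call; adjusted
p < 0.05 is the significance convention throughout.

## Cell-specific networks (CSN) and the network degree matrix (NDM)

For genes x, y and focal cell k, marginal neighborhoods ("boxes") around
cell k contain roughly `box_frac * n` cells each (default 0.1n). With `n_x`,
`n_y` cells in the boxes and `n_xy` in their intersection, the statistic

    rho_xy(k) = sqrt(n-1) (n n_xy - n_x n_y) / sqrt(n_x n_y (n-n_x)(n-n_y))

is asymptotically N(0,1) when x and y are independent. Two numerical
decisions depart from the naive reading and are load-bearing:

- **Box construction.** Boxes are rank windows with ties broken by a
  per-gene seeded shuffle, keeping every box at its nominal size. Admitting
  whole tie blocks instead makes the shared dropout mass of two sparse genes
  a ~70%-of-cells box that always overlaps itself: every inactive cell then
  carries highly significant "coordinated silence" edges, and a TF's
  connectivity peaks *outside* its active state — the opposite of the signal
  the method is meant to expose. Subsampled tie blocks are shuffled
  independently per gene so they do not artificially co-occupy. The
  `tie_seed` is recorded in `CsnParams`.
- **Edge test.** The focal cell always sits inside both of its own boxes,
  which biases the raw statistic upward by about +0.4 standard deviations
  (empirical upper-tail rate 0.047 at a nominal 0.01). Removing the focal
  cell from the counts makes the remaining overlap `n_xy - 1` exactly
  Hypergeometric(n-1, n_x-1, n_y-1) under independence, conditional on the
  box sizes; the per-edge decision is therefore the exact upper-tail
  hypergeometric test at level `alpha` (default 0.01, upper tail only —
  edges denote positive association). The normal approximation on the
  debiased counts still over-calls (0.018) because of the discreteness of
  the overlap count. The exact test measures 0.006 at nominal 0.01:
  conservative, as a discrete exact test must be. Degenerate boxes
  (`n_x <= 1` or `n_x >= n`) make an edge untestable, never significant.

The NDM entry (gene, cell) is the gene's number of significant edges in
that cell. Differential connectivity between a cluster and the rest uses a
two-sided Wilcoxon rank-sum per gene (exact for small tie-free groups,
midrank/normal otherwise) with BH adjustment. Per-cluster edge frequencies
(fraction of member cells where a pair is significant) feed arc-diagram
style summaries. Subset analyses compute boxes on all cells but only subset
pairs; the full all-pairs transcriptome NDM is O(G^2 n^2) and should be
chunked by gene subset.

## Diffusion maps and pseudotime

The kernel is Gaussian on Euclidean distances with per-cell adaptive
bandwidth (distance to the `ceil(k_neighbors/2)`-th neighbor, default
`k_neighbors = 30`), optionally density-normalized (dividing by the product
of row sums) and row-normalized to a Markov transition matrix. The spectrum
is computed through the symmetric conjugate, the trivial eigenvector is
dropped, and components are eigenvalue-scaled eigenvectors with signs fixed
deterministically. Cells with zero bandwidth (exact duplicates — common for
quantized activity scores) receive the median positive bandwidth so they
stay coupled to the graph; the event is reported as a warning. The local
bandwidth makes the transition matrix invariant to global rescaling of the
input, which is asserted numerically.

Pseudotime is the Euclidean distance to a root cell in the eigenspace with
coordinates `psi_i * lambda_i / (1 - lambda_i)`, rescaled to `[0, 1]`. If a
non-trivial eigenvalue is numerically 1 the graph is disconnected and
pseudotime is refused with an error naming the components. The root is
either supplied or selected as the cell of a user-named early cluster
farthest (in component space) from the centroid of the other clusters:
anchoring at an arbitrary early cell is fragile, because a single noisy cell
whose profile resembles a later state drags the whole ordering. Cluster-level
transition summaries average the cell-to-cell transition probabilities over
all ordered cluster pairs. Either the PC embedding of expression or the
regulon activity matrix can serve as the feature space; both recover a
planted linear lineage (see below).

## Preranked enrichment

The running statistic adds `|stat|^p / sum_hits |stat|^p` at gene-set
members and subtracts `1/(N - |S|)` at misses; the enrichment score is the
signed extremum of the walk, the leading edge the hits up to (positive) or
after (negative) it. The null draws `n_perm` random same-size gene sets
from the ranked list — gene permutation, the standard for preranked input —
with all randomness seeded. NES divides ES by the mean magnitude of
same-sign null scores; the p-value is the add-one ("+1/(m+1)") tail
fraction among same-sign null scores, which keeps the permutation test
valid rather than anti-conservative. BH runs across sets; the significance
flag is FDR < 0.05 AND |NES| > 1. Set-size limits default to 5/500. The
ranking metric used by the pipeline for cluster-level enrichment is the
mean log-normalized expression difference (cluster vs rest); it is a
parameter, not a fixed choice.

## Dense-module detection (MCODE)

Vertex weight = k_max × density of the highest k-core of the closed
neighborhood N[v] (0 below the degree cutoff); complexes grow outward from
the highest-weight unvisited seed, adding neighbors whose weight is at
least `seed_weight * (1 - node_score_cutoff)`; included vertices are marked
visited, making modules vertex-disjoint; complexes lacking a `k_core`-core
are dropped; module score = density × size, so a clique K_n scores exactly
n. Defaults: degree cutoff 2, node score cutoff 0.2, K-core 2, reporting
score cutoff 3.0. Edge weights (STRING-style combined scores in [0,1]) are
used only for optional input filtering; the algorithm itself is
topological. "Fluff" and "haircut" post-processing are implemented but off
by default.

## Synthetic data: what it emulates and what it does not

The generator plants everything downstream stages are asked to recover:

- K clusters (default 3 × 200 cells) as equal-width quantile bins of a
  uniform pseudotime; a two-branch option duplicates the upper half of
  pseudotime into a side-branch flag.
- Regulons (default two: a TF plus 10 targets each, active in the first and
  last cluster at fold change 8). Member genes share a per-cell latent
  activity that ramps along pseudotime within the active window (early
  programs decay from the lineage start, late programs rise toward its end)
  with multiplicative jitter uniform in [0.5, 1]. The shared latent is what
  makes member genes co-vary *within* the active cluster — the signal CSN
  measures; a constant fold change would leave them conditionally
  independent given the cluster, and a cluster-blind iid latent would
  decouple activity from the lineage. Both simpler variants were
  implemented first and demonstrably break the respective recoveries.
- Monotone marker trends: 20 up- and 20 down-trending genes with mean
  multiplier `1 + 6t` / `1 + 6(1-t)` — roughly 40% of the universe dynamic,
  as in a differentiating lineage. Weaker trend configurations leave the
  within-cluster ordering unidentifiable (the data's own marker-axis
  ceiling drops to Spearman ~0.66), so recovery tests would measure noise.
- Counts are NegativeBinomial(mean, size = dispersion 2.0) at baseline mean
  1.0, zeroed independently with probability
  `sigmoid(-slope (log mu - midpoint))` (slope 1, midpoint 0, i.e. ~50%
  dropout at baseline; `dropout_slope = 0` disables dropout).
- QC decoys: five `MT-` genes at 0.2× baseline (a few percent of counts in
  healthy cells), hemoglobin genes at zero, `RUNX2` clamped ≥ 1 in intact
  lineage cells (the marker rule must hold deterministically for the
  planted truth to be exact), and `n_qc_bad_cells` cells each violating
  exactly one QC rule. Because the paper-scale gene-count bounds are
  meaningless on a ~150-gene universe, the dataset carries a matched
  `qc_params` (min 10 / max 0.9·G genes, same mito/marker/hemoglobin
  rules) used by its own truth-consistency guarantees.

Not emulated: batch effects, ambient RNA, doublets beyond the gene-count
ceiling, UMI-level noise, and any real gene-gene regulatory topology beyond
the planted sets. Passing recovery tests therefore show the pipeline's
statistics detect the structure they define — not that they would resolve
the much weaker and more confounded structure of a real tissue.

## Problem sizes and determinism

Default validation runs use 600 good cells × ~150 genes, CSN on ~40-gene
subsets (≈800 pairs), 10-seed null calibrations at n = 500, 200-replicate
enrichment type-I simulations at n_perm = 200, and 50-node background
graphs — sizes chosen so the full suite and the reproduction script each
complete in well under a minute on one core while keeping every Monte-Carlo
margin wide. All randomness flows through explicit seeds; the pipeline
derives one child seed per stage from the global seed via CRC32 of the
stage name, so reruns are byte-identical and stages are decoupled.

## Known limitations

- The exact conditional edge test is conservative (discrete); at alpha
  0.01 the realized rate is ~0.006.
- The enrichment score's sign under ranking reversal is ambiguous when the
  walk's maximum and minimum magnitudes tie exactly; magnitude is always
  preserved.
- Activity-based pseudotime inherits the coarseness of the activity matrix:
  with few regulons, within-cluster ordering comes only from the latent
  ramp, and the attainable rank correlation is intrinsically below the
  expression-based one.
- The all-pairs CSN is quadratic in both genes and cells; transcriptome-wide
  runs require gene chunking and patience.
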