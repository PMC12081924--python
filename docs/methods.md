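# Methods

This note records what `scrden` computes, the choices made where the
procedure was genuinely open, and what the synthetic benchmark does and
does not demonstrate.

## Model and procedure

The pipeline treats a genes × cells non-negative matrix as observations
of cells moving along one or more differentiation branches. Its central
object is not expression but the *rank differential*: within each cell,
genes are ranked ascending by expression (ordinal ties broken by gene
index, so every cell's ranks are exactly a permutation of 1..m), and for
each pair of correlated genes the per-cell difference of their ranks is
recorded. Ranks are invariant under any monotone per-cell distortion
(depth, scaling) and degrade gracefully under dropout, which is why the
pair profiles are a more stable substrate for clustering than the raw
matrix.

Stages and their governing quantities:

- **Gene screening.** Name-based removal (shipped regexes `mt-`/`MT-`,
  `Rps`/`Rpl`/`RPS`/`RPL`, `ERCC-`; configurable), then a prevalence
  filter keeping genes expressed (count > 0) in strictly more than
  `expression_fraction_min` (default 0.10) of cells.
- **Winsorisation.** Per gene, entries outside μ ± 4σ (population σ,
  computed once on the unclipped vector) are clipped to the boundary and
  floored at 0. Applying the operator twice can only shrink bounds, so a
  second pass changes no more entries than the first.
- **Log transform.** `log2(x + 1)`; zeros stay zero.
- **Feature selection.** Intrinsic score = variance of log expression
  across cells. Genes above the `intrinsic_cutoff_quantile` (default
  0.90) of scores with mean log expression > `I` (default 1.0) are kept.
  An earlier design scored genes by histogram entropy relative to a
  running-median entropy trend over mean expression; it was abandoned
  because (a) per-gene adaptive binning normalises scale away, and
  (b) wherever co-regulated gene modules dominate a mean regime they set
  the trend themselves and cancel their own signal. Variance has neither
  failure mode, scores a constant gene exactly 0, and ranks
  subpopulation-restricted programmes (branch markers) correctly.
  Histogram entropy at a pooled Freedman–Diaconis bandwidth is still
  reported per gene as a diagnostic.
- **Co-expression.** Pearson correlations with two-sided t-tests
  (n − 2 df); raw p < `pearson_alpha` (default 0.01, BH correction
  optional and off by default); `B₀ = |R|` with zero diagonal; edges
  where `b_ij > b₀` strictly. When `b₀` is not supplied it is selected
  on a grid (0.10–0.95, step 0.05) as the smallest threshold whose
  unweighted graph reaches signed scale-free fit R² ≥ 0.80, falling back
  to the best fit; WGCNA-style fit with 10 equal-width degree bins,
  occupancy fractions regressed on mean degree in log–log space.
  Candidates disconnecting more than half the genes are treated as
  degenerate — a fragmented remnant can fit a power law spuriously well.
- **Edge profiles.** One row per co-expression edge, oriented (smaller
  gene index, larger gene index); raw values are integer rank
  differences in [−(m−1), m−1] and antisymmetric under orientation
  flip; min–max normalisation per cell maps each cell's column to
  [0, 1] (constant columns to 0); the top `cv_top_fraction` (default
  1 %) of rows by CV = sd/mean are kept, never fewer than
  `min_cv_edges` (default 200). The floor exists because the 1 % rule is
  a memory-reduction device calibrated to networks of 10⁵–10⁶ pairs,
  where it retains thousands of profiles; on a few hundred edges it
  would crush the feature space to a handful of rows.
- **Ensemble clustering.** PCA (≤ 30 components), t-SNE (2D, perplexity
  min(30, (n−1)/3)) and UMAP (2D), all seeded. Per view: Euclidean
  distances ρ; ρ_i = mean distance to the k = `knn_k` (default 30)
  nearest neighbours; ε_ij = (ρ_i + ρ_j + ρ_ij)/3 floored at 1e−12;
  W = exp(−ρ²/(μ ε)) with μ = `kernel_mu` (default 0.5); P with
  diagonal ½ and off-diagonal rows summing to ½; S row-normalised
  (halved) over the k-neighbourhood. Fusion iterates
  `P⁽ᵛ⁾ ← S⁽ᵛ⁾ · mean(P⁽ᵏ⁾, k≠v) · S⁽ᵛ⁾ᵀ`, then re-symmetrises and
  renormalises every view to the P structure (the raw update does not
  preserve it, and the eigengap step needs it). The convergence test is
  prospective: the update that would change entries by less than
  `snf_tol` is discarded, so an infinite tolerance performs zero
  iterations and returns the symmetrised mean of the initial views.
  The fused affinity is the symmetrised view mean.
- **Cluster count.** Eigenvalues of the unnormalised Laplacian
  `L = D − E` ascending (normalised variant behind a flag); gaps
  λ_{i+1} − λ_i for i in 2..15; of the two largest gaps the index of the
  *smaller value* is taken (ties toward the smaller index). The
  alternative reading — the smaller *index* of the top two — is a config
  option. The search starting at 2 means one cluster is never
  auto-selected; a user-supplied count always wins.
- **Spectral clustering.** Rows of the first p Laplacian eigenvectors,
  length-normalised, k-means with 50 restarts at a fixed seed, labels
  renumbered by decreasing cluster size.
- **Pseudotime.** Start cluster = highest mean marker z-score. Cluster
  centroids in the t-SNE plane; D_u = centroid distance to start. Default
  mode `normalized_distance` (T_u = D_u / max D) keeps geometric spacing,
  matching the unevenly spaced stage times the method reports in
  practice; `rank` mode ((rank−1)/(p−1)) is the literal ranking variant.
  All cells of a cluster share its T.
- **Lineages.** MST over cluster centroids (Euclidean), rooted at the
  start cluster; root-to-leaf paths are lineages, reported in terminal-T
  order. Pseudotime is globally normalised, so shared stem segments agree
  across paths. Monotonicity of T along a path is expected for elongated
  trajectories but not enforced — MST paths on pathological layouts can
  zigzag.
- **Stage networks.** For each cluster pseudotime, weight of an oriented
  key-gene pair = mean of its normalised profile over the stage's cells;
  H + Hᵀ symmetrises the once-stored matrix. Averaging the *raw* signed
  rank differences and then symmetrising would cancel every weight
  identically, so the normalised profiles are the operative quantity.
  Edges below `edge_display_threshold` (default 0.2, strict) are
  discarded. Pairs outside the co-expression edge set are non-edges, not
  zero-weight edges, for degree and triangle purposes. Diversity(i) =
  −Σ p_ij log p_ij / log k_i over incident weights (0 when k_i ≤ 1);
  CO(i) = 2 TR(i)/(k_i(k_i−1)) on the unweighted skeleton.
- **Metrics.** POS normalises the pair sum Σ g(i,j) by D = the maximal
  attainable positive sum (the pair sum of a time-sorted arrangement),
  which makes the endpoint identities exact: +1 iff time-sorted, −1 iff
  reverse-sorted, ties contribute 0, all-equal times define POS = 0.
  The robust score counts concordant unordered pairs over the *union* of
  two orderings — cells present in only one ordering contribute
  discordant pairs. The bubble-sort index is 1 − inversions/C(n,2),
  giving the identity Kendall τ = 2·BSI − 1 on duplicate-free orders.
  Gaussian perturbation adds per-gene N(0, (k·σ_g)²) noise on the log
  scale (uniform meaning of "k %" across genes), floored at 0.

## Synthetic data

`simulate_branching` draws latent times t ~ U[0,1], assigns each cell a
branch (expression is branch-independent before the branch point,
default 0.4), and mixes six gene programmes: ramp-up and ramp-down
(linear within a per-gene activation window), switch-like (sigmoid,
midpoint U[0.2, 0.8]), branch-specific (sigmoidal activation anchored to
zero at the branch point — fate markers switch on rapidly after
commitment), housekeeping (constant mean U[2, 8]) and low noise genes.
Baselines (U[0.5, 2]) and amplitudes (U[40, 80] counts) vary per gene so
the correlation structure has modules rather than one clique. Counts are
negative-binomial (default size 10) with zero-inflation probability
`dropout_rate · exp(−mean/2)`. A fixed seed makes output bit-identical.

What it emulates: dropout, overdispersion, monotone/sigmoidal programmes,
a shared root with diverging branches. What it does not: library-size
and batch effects, gene–gene co-expression beyond shared time dependence
(no copula structure), doublets, cell-cycle signal. Passing tests
demonstrate that the machinery recovers structure its own generative
model contains — not performance on any particular tissue.

## Benchmark conditions

The recovery tests run at 400 genes × 300 cells, seed 1. The
co-expression hard threshold is fixed at 0.3 there: degree-distribution
fits are not meaningful on 40-gene feature panels (every dynamic gene
correlates with every other through time), and a moderate fixed
threshold keeps the anti-correlated pairs whose rank differences carry
the trajectory signal. The linear run uses 8 clusters and the
bifurcating run 4, mirroring the cluster counts chosen empirically for
the corresponding published linear and bifurcating datasets. The
clustering reference partition discretises truth into branch × time-bin
classes (quantile bins; two root bins, one bin per branch for the
4-cluster benchmark). The robustness protocol perturbs the log matrix at
k = 5/10/20 % with 5 replicates per level and compares orderings to the
unperturbed run. These sizes keep the full suite under a minute of
pipeline time while leaving every stage non-trivial.

## Numerical choices and degenerate inputs

- Ordinal (stable) rank ties: average ranks would break the
  "permutation of 1..m" invariant the profile arithmetic relies on.
- Constant min–max columns map to 0 (neutral signal), configurable.
- Zero-variance genes get correlation 0 / p-value 1 rather than NaN.
- ε and row-sum denominators are floored at 1e−12; duplicate embedded
  points therefore fuse rather than crash.
- Diversity and CO are defined as 0 at degree ≤ 1 (log k or k−1
  vanishes).
- Eigengap ties break toward the smaller index; k-means uses a fixed
  seed and 50 restarts; cluster labels are size-ordered so runs are
  comparable.
- All-equal collection times define POS = 0 with a warning (D = 0).

## Known limitations

- The intrinsic-variability score is marginal (per-gene): it cannot
  distinguish regulatory from technical variance when both produce the
  same marginal spread; a mean-variance-trend correction is deliberately
  not applied (see above).
- Automatic hard-threshold selection needs enough genes (roughly
  hundreds) for a degree distribution to be informative; small panels
  should set `hard_threshold_b0` explicitly.
- Pseudotime is cluster-level by design; within-cluster ordering is
  arbitrary (stable by cell index), bounding POS away from 1 even for
  perfect cluster recovery.
- t-SNE centroid geometry drives pseudotime and lineages; t-SNE's global
  distance distortions can misorder distant stages. The fused affinity
  is used for clustering only, as specified by the procedure.
- Lineage derivation assumes the MST of centroids reflects the true
  branching; near-equidistant branch tips can be chained instead of
  split.
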