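# scrden

Gene **r**ank **d**ifferential **e**xpression **n**etworks for single-cell
RNA-seq: stable cell clustering, branch-aware pseudotime and per-stage
gene-network dynamics.

## The problem and the idea

Raw scRNA-seq expression values are noisy — dropout events, depth
differences and bursting make per-gene values unstable across cells, and
trajectory inference built directly on them inherits that instability.
`scrden` replaces values with *within-cell gene ranks* and works with the
**rank differences of correlated gene pairs**, which are far more stable
under technical noise. The pipeline:

1. **Preprocess** — screen mitochondrial/ribosomal/spike-in genes and
   genes expressed in ≤ 10 % of cells; winsorise each gene to
   μ ± 4σ; transform `A₁ = log₂(A₀ + 1)`; keep high intrinsic-variability
   genes with mean log expression above a threshold *I*, giving the
   feature matrix `E(m×n)`.
2. **Co-expression network** — Pearson correlations `R(m×m)` with a
   two-sided t-test, keep pairs with *p* < 0.01, take `B₀ = |R|` and a
   hard threshold `b₀` (user-set or chosen where the thresholded graph's
   degree distribution best fits a scale-free law): the graph *B*.
3. **Rank network** — within each cell rank all genes ascending
   (`C₀`, a permutation of 1..m per cell); for every edge
   (g_k, g_l) of *B* form the per-cell profile
   `c_gt = rank(g_k, t) − rank(g_l, t)`; min–max normalise per cell to
   [0, 1]; keep the top 1 % of profiles by coefficient of variation.
4. **Ensemble clustering** — embed cells by PCA, t-SNE and UMAP over the
   profiles; per view build a local-scaling kernel
   `W_ij = exp(−ρ²/(μ ε_ij))` with `ε_ij = (ρ_i + ρ_j + ρ_ij)/3`, its
   row-stochastic form *P* (diagonal ½) and k-NN sparse kernel *S*; fuse
   the views by iterated cross-diffusion `P⁽ᵛ⁾ ← S⁽ᵛ⁾ · mean(P⁽ᵏ⁾, k≠v) ·
   S⁽ᵛ⁾ᵀ` into one affinity *E*; choose the cluster count *p* from the
   eigengaps of the Laplacian `L = D − E` and cluster spectrally.
5. **Trajectory** — a marker-designated start cluster gets pseudotime
   T = 0; every other cluster's T comes from its t-SNE centroid distance
   to the start centroid (normalised, or rank-based); lineages are the
   root-to-leaf paths of the minimum spanning tree over centroids.
6. **Dynamics** — at each stage (cluster) build a symmetric gene network
   whose edge weights are stage means of the normalised rank-difference
   profiles, discard edges below 0.2, and track per-node **diversity**
   (scaled Shannon entropy of incident weights, `SE(i)/log k_i`) and
   **clustering coefficient** (`2·TR(i)/(k_i(k_i−1))`) along each lineage.
7. **Evaluation** — pseudotemporal ordering score (POS ∈ [−1, 1]),
   robust score (concordant pair fraction between orderings inferred from
   original and Gaussian-perturbed data, k·σ noise at k = 5/10/20 %),
   bubble-sort index, Kendall τ, ARI and NMI.

A built-in simulator (`scrden.simulate_branching`) generates branching
negative-binomial counts with dropout and known ground truth, so the
whole pipeline is testable without downloads.

## Worked example

```python
from scrden import PipelineConfig, run_pipeline, simulate_branching
from scrden.metrics import pos_score

X, truth = simulate_branching(n_genes=400, n_cells=300, n_branches=2, seed=1)
config = PipelineConfig(n_clusters=4, hard_threshold_b0=0.3, random_seed=1)
root_markers = truth.genes_in_module("ramp_down")[:5]   # high at t = 0
result = run_pipeline(X, config, start_markers=root_markers)

print("feature genes :", result.E.n_genes)
print("network edges :", result.graph.n_edges)
print("edge profiles :", result.profiles.n_edges)
print("cluster sizes :", result.labels.cluster_sizes())
print("pseudotime    :", {c: round(t, 2) for c, t in sorted(result.model.cluster_T.items())})
print("lineages      :", result.model.paths)
times = dict(zip(X.cell_ids, truth.true_time))
print("POS vs truth  :", round(pos_score(result.cell_ordering(), times), 3))
```

prints

```
feature genes : 40
network edges : 778
edge profiles : 200
cluster sizes : {1: 133, 2: 79, 3: 64, 4: 24}
pseudotime    : {1: 0.0, 2: 1.0, 3: 0.89, 4: 0.57}
lineages      : [[1, 4, 3], [1, 2]]
POS vs truth  : 0.771
```

Cluster 1 (the start, T = 0) holds the shared root; the minimum spanning
tree over the four centroids splits into two lineages (1→4→3 and 1→2),
matching the simulated bifurcation; POS 0.77 says the coarse 4-stage
ordering agrees strongly with the hidden simulation time (an 8-cluster
run on linear data reaches POS ≈ 0.94).

The same run is available from the shell:

```bash
scrden simulate --n-genes 400 --n-cells 300 --n-branches 2 --seed 1 --outdir sim
scrden run --input sim/matrix.tsv --markers g0080,g0081 --outdir out
scrden evaluate --truth sim/truth.tsv --run out
```

## Layout

```
src/scrden/
  containers.py       genes × cells matrix container
  config.py           all thresholds and hyperparameters
  io_formats.py       dense CSV/TSV + 10x MatrixMarket + edge lists
  synthetic_data.py   branching NB + dropout simulator with ground truth
  preprocess.py       screening, winsorising, log2, feature selection
  coexpression.py     Pearson network with hard threshold
  rank_network.py     within-cell ranks, edge profiles, CV filter
  ensemble_cluster.py embeddings, kernels, fusion, spectral clustering
  trajectory.py       start cluster, centroid pseudotime, lineages, markers
  dynamic_network.py  per-stage networks, diversity, clustering coefficient
  metrics.py          POS, robust score, BSI, Kendall, ARI/NMI, perturbation
  pipeline.py         orchestration + robustness protocol
  cli.py              `scrden` command-line interface
```

See `docs/methods.md` for the model details, parameter defaults and known
limitations.
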