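"""Branch-aware pseudotime from cluster centroids.

Clusters receive a pseudotime from their centroid's Euclidean distance to
a marker-designated start cluster in the t-SNE plane: either the
distance normalised by the largest distance (default, so stages keep
their geometric spacing) or the ascending rank of the distance rescaled
to [0, 1]. Lineage paths are the root-to-leaf paths of the minimum
spanning tree over cluster centroids, rooted at the start cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .containers import GeneExpressionMatrix, ValidationError
from .ensemble_cluster import ClusterAssignment

logger = logging.getLogger(__name__)


@dataclass
class TrajectoryModel:
    """Cluster-level pseudotime plus lineage structure."""

    start_cluster: int
    centroids: Dict[int, np.ndarray]
    distances: Dict[int, float]
    cluster_T: Dict[int, float]
    cell_ids: list
    labels: np.ndarray
    mode: str = "normalized_distance"
    paths: Optional[List[List[int]]] = None

    @property
    def cell_T(self) -> np.ndarray:
        return np.array([self.cluster_T[l] for l in self.labels])

    def cell_ordering(self) -> list:
        """Cells sorted by pseudotime, ties broken by cell index."""
        T = self.cell_T
        order = np.lexsort((np.arange(len(T)), T))
        return [self.cell_ids[i] for i in order]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cell_id": self.cell_ids,
            "cluster": self.labels,
            "pseudotime": self.cell_T,
        }).set_index("cell_id")


def choose_start_cluster(X: GeneExpressionMatrix, labels: ClusterAssignment,
                         start_markers: Sequence[str]) -> int:
    """Cluster with the highest mean marker expression (mean of z-scores).

    ``X`` should be the full (pre-feature-selection) log matrix so that
    markers filtered out upstream are still usable.
    """
    present = [g for g in start_markers if g in X.gene_ids]
    if not present:
        raise ValidationError(
            f"none of the start markers {list(start_markers)[:5]} are in "
            "the matrix")
    if len(present) < len(start_markers):
        logger.warning("%d of %d start markers missing from matrix",
                       len(start_markers) - len(present), len(start_markers))
    idx = [X.gene_index(g) for g in present]
    sub = X.values[idx]
    mu = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, keepdims=True)
    z = (sub - mu) / np.where(sd == 0, 1.0, sd)
    score = z.mean(axis=0)
    best, best_score = None, -np.inf
    for cl in sorted(set(labels.labels.tolist())):
        s = score[labels.labels == cl].mean()
        logger.info("start-marker score cluster %d: %.3f", cl, s)
        if s > best_score:
            best, best_score = cl, s
    return int(best)


def cluster_pseudotime(coords: np.ndarray, labels: ClusterAssignment,
                       start_cluster: int,
                       mode: str = "normalized_distance") -> TrajectoryModel:
    """Assign each cluster (hence each cell) a pseudotime in [0, 1].

    ``coords`` are per-cell t-SNE coordinates. The start cluster always
    gets T = 0. Mode ``"normalized_distance"`` sets
    ``T_u = D_u / max(D)``; mode ``"rank"`` uses the ascending rank of
    ``D_u`` rescaled by ``(rank - 1) / (p - 1)``.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] != len(labels.cell_ids):
        raise ValidationError("coords and labels cover different cells")
    clusters = sorted(set(labels.labels.tolist()))
    if start_cluster not in clusters:
        raise ValidationError(f"start cluster {start_cluster} not in labels")
    centroids = {cl: coords[labels.labels == cl].mean(axis=0)
                 for cl in clusters}
    d1 = centroids[start_cluster]
    D = {cl: float(np.linalg.norm(centroids[cl] - d1)) for cl in clusters}
    p = len(clusters)
    if p == 1:
        logger.warning("single cluster: all pseudotimes set to 0")
        T = {clusters[0]: 0.0}
    elif mode == "normalized_distance":
        dmax = max(D.values())
        T = {cl: (D[cl] / dmax if dmax > 0 else 0.0) for cl in clusters}
    elif mode == "rank":
        ordered = sorted(clusters, key=lambda cl: (D[cl], cl))
        T = {cl: r / (p - 1) for r, cl in enumerate(ordered)}
    else:
        raise ValidationError(f"unknown pseudotime mode {mode!r}")
    return TrajectoryModel(start_cluster, centroids, D, T,
                           list(labels.cell_ids), labels.labels.copy(), mode)


def derive_lineage_paths(model: TrajectoryModel) -> List[List[int]]:
    """Root-to-leaf lineages from the centroid minimum spanning tree.

    The complete graph on cluster centroids with Euclidean edge weights
    is reduced to its MST and rooted at the start cluster; each path to a
    leaf is one lineage. Paths are reported sorted by the pseudotime of
    their terminal cluster. The result is also stored on ``model``.
    """
    clusters = sorted(model.centroids)
    g = nx.Graph()
    g.add_nodes_from(clusters)
    for i, a in enumerate(clusters):
        for b in clusters[i + 1:]:
            w = float(np.linalg.norm(model.centroids[a] - model.centroids[b]))
            g.add_edge(a, b, weight=w)
    if len(clusters) == 1:
        model.paths = [[clusters[0]]]
        return model.paths
    mst = nx.minimum_spanning_tree(g)
    root = model.start_cluster
    leaves = [n for n in mst.nodes
              if mst.degree(n) == 1 and n != root]
    if not leaves:  # root is the single leaf of a 1-edge tree edge case
        leaves = [n for n in mst.nodes if n != root]
    paths = [nx.shortest_path(mst, root, leaf) for leaf in leaves]
    paths.sort(key=lambda path: (model.cluster_T[path[-1]], path))
    model.paths = paths
    return paths


def identify_marker_genes(X: GeneExpressionMatrix, labels: ClusterAssignment,
                          log2fc_min: float = 1.0, alpha: float = 0.05,
                          min_cells: int = 3) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum markers per cluster.

    ``X`` is the log-scale matrix over all screened genes. For each
    cluster, every gene gets a two-sided rank-sum p-value (BH-adjusted
    within the cluster) and a fold change
    ``log2((mean_in + 1) / (mean_rest + 1))`` on the matrix values;
    markers satisfy ``log2FC > log2fc_min`` and adjusted p < ``alpha``.
    Clusters smaller than ``min_cells`` are skipped with a warning.
    """
    rows = []
    v = X.values
    for cl in sorted(set(labels.labels.tolist())):
        mask = labels.labels == cl
        if mask.sum() < min_cells:
            logger.warning("cluster %d has %d cells (<%d); skipped",
                           cl, int(mask.sum()), min_cells)
            continue
        if (~mask).sum() == 0:
            continue
        inside, outside = v[:, mask], v[:, ~mask]
        stat = scipy.stats.mannwhitneyu(inside, outside, axis=1,
                                        alternative="two-sided")
        pvals = np.asarray(stat.pvalue)
        qvals = multipletests(pvals, method="fdr_bh")[1]
        l2fc = np.log2((inside.mean(axis=1) + 1.0)
                       / (outside.mean(axis=1) + 1.0))
        sig = (l2fc > log2fc_min) & (qvals < alpha)
        for gi in np.flatnonzero(sig):
            rows.append({"cluster": cl, "gene": X.gene_ids[gi],
                         "log2fc": l2fc[gi], "pvalue": pvals[gi],
                         "qvalue": qvals[gi]})
    df = pd.DataFrame(rows, columns=["cluster", "gene", "log2fc",
                                     "pvalue", "qvalue"])
    if len(df):
        df = df.sort_values(["cluster", "log2fc"],
                            ascending=[True, False]).reset_index(drop=True)
    return df
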