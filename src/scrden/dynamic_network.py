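"""Per-stage gene rank differential networks and their topology.

For each pseudotime stage (cluster) a symmetric weighted network over a
key-gene set is built: the weight of a pair is the mean of its
normalised rank-difference profile over the stage's cells, mirrored to a
symmetric matrix. Edges below a display threshold are discarded, and two
node statistics summarise topology: diversity (scaled Shannon entropy of
incident edge weights) and the clustering coefficient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .containers import ValidationError
from .ensemble_cluster import ClusterAssignment
from .rank_network import EdgeProfileMatrix
from .trajectory import TrajectoryModel

logger = logging.getLogger(__name__)


@dataclass
class StageNetwork:
    """Symmetric weighted gene graph at one pseudotime stage.

    ``weights`` is the symmetrised matrix over ``genes``; ``present``
    marks pairs that exist in the co-expression edge universe — absent
    pairs are non-edges, not zero-weight edges, for degree and triangle
    purposes.
    """

    pt: float
    genes: list
    weights: np.ndarray
    present: np.ndarray
    threshold: Optional[float] = None

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def adjacency(self) -> np.ndarray:
        """Unweighted edge skeleton (present and weight > 0)."""
        return self.present & (self.weights > 0)

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.genes)
        ii, jj = np.nonzero(np.triu(self.adjacency(), k=1))
        for i, j in zip(ii, jj):
            g.add_edge(self.genes[i], self.genes[j],
                       weight=float(self.weights[i, j]))
        return g


def stage_network(c: EdgeProfileMatrix, labels: ClusterAssignment,
                  model: TrajectoryModel, key_genes: Sequence[str],
                  pt: float, atol: float = 1e-9) -> StageNetwork:
    """Build the rank differential network at pseudotime ``pt``.

    For every stored co-expression pair between two key genes the weight
    is the mean of the normalised profile over the cells whose cluster
    pseudotime equals ``pt``; the once-stored oriented matrix H is then
    mirrored (H + H^T) into the symmetric stage network.
    """
    if c.normalization != "minmax":
        raise ValidationError("stage networks need min-max normalised profiles")
    stage_clusters = [cl for cl, t in model.cluster_T.items()
                      if abs(t - pt) <= atol]
    if not stage_clusters:
        raise ValidationError(f"no cluster has pseudotime {pt}")
    cells = np.isin(labels.labels, stage_clusters)
    if not cells.any():
        raise ValidationError(f"no cells at pseudotime {pt}")
    key_genes = list(dict.fromkeys(key_genes))  # dedupe, keep order
    gpos = {g: i for i, g in enumerate(sorted(key_genes))}
    genes = sorted(key_genes)
    m = len(genes)
    H = np.zeros((m, m))
    present = np.zeros((m, m), dtype=bool)
    touched = set()
    stage_vals = c.values[:, cells]
    for row, (a, b) in enumerate(c.edges):
        if a in gpos and b in gpos:
            i, j = gpos[a], gpos[b]
            H[i, j] = stage_vals[row].mean()
            present[i, j] = True
            touched.update((a, b))
    isolated = set(genes) - touched
    if isolated:
        logger.warning("key genes absent from all profile edges: %s",
                       sorted(isolated))
    weights = H + H.T
    present = present | present.T
    return StageNetwork(float(pt), genes, weights, present)


def threshold_network(net: StageNetwork, threshold: float = 0.2,
                      ) -> StageNetwork:
    """Discard edges with weight strictly below ``threshold``.

    A weight exactly equal to the threshold survives.
    """
    keep = net.present & (net.weights >= threshold)
    weights = np.where(keep, net.weights, 0.0)
    return StageNetwork(net.pt, list(net.genes), weights, keep, threshold)


def node_diversity(net: StageNetwork) -> pd.Series:
    """Scaled Shannon entropy of each node's incident edge weights.

    With normalised incident weights ``p_ij = w_ij / sum_l w_il``,
    diversity is ``-sum p log p / log k``; nodes of degree <= 1 score 0.
    """
    adj = net.adjacency()
    out = np.zeros(net.n_genes)
    for i in range(net.n_genes):
        nbrs = np.flatnonzero(adj[i])
        k = len(nbrs)
        if k <= 1:
            continue
        w = net.weights[i, nbrs]
        p = w / w.sum()
        p = p[p > 0]
        out[i] = float(-(p * np.log(p)).sum() / np.log(k))
    return pd.Series(out, index=net.genes, name="diversity")


def node_cluster_coefficient(net: StageNetwork) -> pd.Series:
    """Fraction of closed triangles among each node's neighbours.

    ``CO(i) = 2 TR(i) / (k_i (k_i - 1))`` with ``TR(i)`` the number of
    edges among i's neighbours on the unweighted skeleton; degree <= 1
    scores 0.
    """
    adj = net.adjacency().astype(int)
    np.fill_diagonal(adj, 0)
    deg = adj.sum(axis=1)
    tri = np.diag(adj @ adj @ adj) / 2  # closed triangles through each node
    out = np.zeros(net.n_genes)
    ok = deg > 1
    out[ok] = 2.0 * tri[ok] / (deg[ok] * (deg[ok] - 1))
    return pd.Series(out, index=net.genes, name="cluster_coefficient")


def dynamics_along_path(c: EdgeProfileMatrix, labels: ClusterAssignment,
                        model: TrajectoryModel, key_genes: Sequence[str],
                        path: Sequence[int], threshold: float = 0.2,
                        ) -> Tuple[List[StageNetwork], pd.DataFrame]:
    """Stage networks along one lineage path, in pseudotime order.

    Returns the thresholded networks and a per-stage summary of mean
    node diversity and mean clustering coefficient.
    """
    stages = sorted(path, key=lambda cl: model.cluster_T[cl])
    nets, rows = [], []
    for cl in stages:
        pt = model.cluster_T[cl]
        net = threshold_network(
            stage_network(c, labels, model, key_genes, pt), threshold)
        nets.append(net)
        div = node_diversity(net)
        co = node_cluster_coefficient(net)
        rows.append({"cluster": cl, "pseudotime": pt,
                     "n_edges": int(np.triu(net.adjacency(), 1).sum()),
                     "mean_diversity": float(div.mean()),
                     "mean_cluster_coefficient": float(co.mean())})
    return nets, pd.DataFrame(rows)
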