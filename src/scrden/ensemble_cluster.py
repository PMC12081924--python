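"""Ensemble clustering of cells from the edge-profile matrix.

Cells are embedded three ways (PCA, t-SNE, UMAP), each embedding yields a
local-scaling similarity kernel (full kernel ``P``, sparse k-NN kernel
``S``), the kernels are fused by iterated cross-diffusion in the style of
similarity network fusion, and the fused affinity is clustered by
spectral clustering with the eigengap rule choosing the cluster count.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import scipy.spatial.distance
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .containers import ValidationError
from .rank_network import EdgeProfileMatrix

logger = logging.getLogger(__name__)

_EPS_FLOOR = 1e-12


@dataclass
class EmbeddingSet:
    """PCA / t-SNE / UMAP cell coordinates over one cell set."""

    pca: np.ndarray
    tsne: np.ndarray
    umap: np.ndarray
    cell_ids: list
    seed: int = 0

    def views(self) -> List[np.ndarray]:
        return [self.pca, self.tsne, self.umap]


@dataclass
class FusedAffinity:
    """Fused cell-cell similarity with its spectral diagnostics."""

    E: np.ndarray
    cell_ids: list
    eigenvalues: Optional[np.ndarray] = None
    eigengaps: Optional[np.ndarray] = None
    n_clusters: Optional[int] = None
    n_iterations: int = 0


@dataclass
class ClusterAssignment:
    """Per-cell cluster labels in 1..p, numbered by decreasing size."""

    cell_ids: list
    labels: np.ndarray

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max())

    def cluster_sizes(self) -> dict:
        lab, cnt = np.unique(self.labels, return_counts=True)
        return dict(zip(lab.tolist(), cnt.tolist()))

    def cells_in(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster)


def embed_views(c: EdgeProfileMatrix, seed: int = 0,
                pca_dims: int = 30) -> EmbeddingSet:
    """Embed cells (columns of the edge-profile matrix) three ways.

    PCA keeps up to ``pca_dims`` components; t-SNE and UMAP project to
    two dimensions with the given seed so repeated calls are identical.
    """
    X = c.values.T  # cells x edge features
    n = X.shape[0]
    if n < 3:
        raise ValidationError("need at least 3 cells to embed")
    n_comp = min(pca_dims, n - 1, X.shape[1])
    pca = PCA(n_components=n_comp, random_state=seed).fit_transform(X)
    perplexity = min(30.0, max(2.0, (n - 1) / 3.0))
    tsne = TSNE(n_components=2, random_state=seed, perplexity=perplexity,
                init="pca").fit_transform(X)
    import umap  # deferred: numba compilation is slow at import

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        um = umap.UMAP(n_components=2, random_state=seed,
                       n_neighbors=min(15, n - 1)).fit_transform(X)
    return EmbeddingSet(pca, np.asarray(tsne, float), np.asarray(um, float),
                        list(c.cell_ids), seed)


def local_scaling_kernel(coords: np.ndarray, k: int = 30, mu: float = 0.5,
                         ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Local-scaling similarity kernels from one embedding.

    With ``rho`` the pairwise Euclidean distances, ``rho_i`` the mean
    distance of cell i to its k nearest neighbours and
    ``eps_ij = (rho_i + rho_j + rho_ij) / 3``, the dense kernel is
    ``W_ij = exp(-rho_ij^2 / (mu * eps_ij))``. ``P`` renormalises W so
    each row's off-diagonal mass is 1/2 and the diagonal is exactly 1/2;
    ``S`` row-normalises W over the k-neighbourhood (halved) and is zero
    elsewhere.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if not 1 <= k < n:
        raise ValidationError(f"k must satisfy 1 <= k < n_cells, got {k}")
    if mu <= 0:
        raise ValidationError("mu must be positive")
    D = scipy.spatial.distance.squareform(
        scipy.spatial.distance.pdist(coords))
    # k nearest neighbours excluding self
    order = np.argsort(D + np.diag(np.full(n, np.inf)), axis=1,
                       kind="stable")
    nbr = order[:, :k]
    rho_i = np.take_along_axis(D, nbr, axis=1).mean(axis=1)
    eps = (rho_i[:, None] + rho_i[None, :] + D) / 3.0
    small = eps < _EPS_FLOOR
    if small.any():
        logger.info("local_scaling_kernel: flooring %d tiny scales",
                    int(small.sum()))
        eps = np.maximum(eps, _EPS_FLOOR)
    W = np.exp(-(D ** 2) / (mu * eps))
    P = _renormalize(W)
    S = np.zeros_like(W)
    mask = np.zeros_like(W, dtype=bool)
    np.put_along_axis(mask, nbr, True, axis=1)
    denom = np.where(mask, W, 0.0).sum(axis=1, keepdims=True)
    denom = np.maximum(denom, _EPS_FLOOR)
    S[mask] = (W / (2.0 * denom))[mask]
    return W, P, S


def _renormalize(W: np.ndarray) -> np.ndarray:
    """Impose the full-kernel structure: diagonal 1/2, off-diagonal rows
    summing to 1/2 (so every row sums to 1)."""
    off = W.copy()
    np.fill_diagonal(off, 0.0)
    denom = np.maximum(off.sum(axis=1, keepdims=True), _EPS_FLOOR)
    P = off / (2.0 * denom)
    np.fill_diagonal(P, 0.5)
    return P


def fuse_views(kernels: Sequence[Tuple[np.ndarray, np.ndarray]],
               iters_max: int = 20, tol: float = 1e-6,
               return_history: bool = False):
    """Fuse per-view kernels by iterated cross-diffusion.

    Each sweep updates every view from the previous iterate,
    ``P_v <- S_v @ mean(P_k, k != v) @ S_v.T``, then re-symmetrises and
    renormalises each view to the row-stochastic structure. Iteration
    stops when the next update would change any entry by less than
    ``tol`` (the sub-``tol`` update is not applied) or at ``iters_max``.
    The fused affinity is the symmetrised mean of the final views.
    """
    if len(kernels) < 2:
        raise ValidationError(
            "fusion needs at least 2 views; run spectral clustering "
            "directly on the single view's P instead")
    P_cur = [np.array(P, dtype=float) for P, _ in kernels]
    S = [np.asarray(Sv, dtype=float) for _, Sv in kernels]
    n_views = len(kernels)
    history = [[p.copy() for p in P_cur]]
    n_iter = 0
    for _ in range(iters_max):
        total = sum(P_cur)
        new = []
        for v in range(n_views):
            cross = (total - P_cur[v]) / (n_views - 1)
            upd = S[v] @ cross @ S[v].T
            upd = (upd + upd.T) / 2.0
            new.append(_renormalize(upd))
        change = max(np.abs(nv - ov).max()
                     for nv, ov in zip(new, P_cur))
        if change < tol:
            break
        P_cur = new
        n_iter += 1
        if return_history:
            history.append([p.copy() for p in P_cur])
    E = sum(P_cur) / n_views
    E = (E + E.T) / 2.0
    logger.info("fuse_views: %d iterations", n_iter)
    if return_history:
        return E, n_iter, history
    return E, n_iter


def graph_laplacian(E: np.ndarray, normalized: bool = False) -> np.ndarray:
    """Unnormalised (default) or symmetric-normalised graph Laplacian."""
    d = E.sum(axis=1)
    L = np.diag(d) - E
    if normalized:
        with np.errstate(divide="ignore"):
            inv = 1.0 / np.sqrt(np.maximum(d, _EPS_FLOOR))
        L = inv[:, None] * L * inv[None, :]
    return L


def eigengap_cluster_count(E: np.ndarray, i_max: int = 15,
                           rule: str = "smaller_value",
                           normalized: bool = False,
                           ) -> Tuple[int, np.ndarray, np.ndarray]:
    """Cluster count from the Laplacian eigengap profile.

    Eigenvalues of ``L = D - E`` are sorted ascending and the gaps
    ``lambda_{i+1} - lambda_i`` computed for ``i`` in ``2..i_max``. Of the
    two largest gaps, ``rule="smaller_value"`` returns the index of the
    smaller gap value and ``rule="smaller_index"`` the smaller index;
    ties break toward the smaller index either way. Returns
    ``(p, eigenvalues, gaps)`` with ``gaps[i]`` aligned to index ``i + 2``.
    """
    E = np.asarray(E, dtype=float)
    if not np.allclose(E, E.T, atol=1e-8):
        raise ValidationError("affinity matrix is not symmetric")
    n = E.shape[0]
    lam = np.linalg.eigvalsh(graph_laplacian(E, normalized))
    hi = min(i_max, n - 1)
    if hi < 2:
        return 1, lam, np.array([])
    idx = np.arange(2, hi + 1)           # candidate cluster counts
    gaps = lam[idx] - lam[idx - 1]       # lambda_{i+1} - lambda_i, 1-based
    order = np.lexsort((idx, -gaps))     # by gap desc, index asc
    top2 = order[:2]
    if len(top2) == 1:
        p = int(idx[top2[0]])
    elif rule == "smaller_value":
        a, b = top2
        # the pair member with the smaller gap value; tie -> smaller index
        if gaps[a] == gaps[b]:
            p = int(min(idx[a], idx[b]))
        else:
            p = int(idx[a] if gaps[a] < gaps[b] else idx[b])
    else:  # smaller_index
        p = int(min(idx[top2[0]], idx[top2[1]]))
    return p, lam, gaps


def spectral_cluster(E: np.ndarray, p: int, seed: int = 0,
                     cell_ids: Optional[list] = None, n_init: int = 50,
                     normalized: bool = False) -> ClusterAssignment:
    """Spectral clustering of the fused affinity into ``p`` clusters.

    Cells are embedded in the eigenvectors of the ``p`` smallest
    Laplacian eigenvalues, rows are length-normalised, and k-means with a
    fixed seed and ``n_init`` restarts assigns labels, renumbered by
    decreasing cluster size (1 = largest).
    """
    E = np.asarray(E, dtype=float)
    n = E.shape[0]
    if p < 1:
        raise ValidationError("p must be >= 1")
    if p > n:
        raise ValidationError(f"p={p} exceeds {n} cells")
    if cell_ids is None:
        cell_ids = list(range(n))
    if p == 1:
        return ClusterAssignment(list(cell_ids), np.ones(n, dtype=int))
    L = graph_laplacian(E, normalized)
    _, vec = np.linalg.eigh(L)
    U = vec[:, :p]
    norms = np.linalg.norm(U, axis=1, keepdims=True)
    U = U / np.maximum(norms, _EPS_FLOOR)
    km = KMeans(n_clusters=p, n_init=n_init, random_state=seed).fit(U)
    raw = km.labels_
    sizes = np.bincount(raw, minlength=p)
    order = np.lexsort((np.arange(p), -sizes))
    relabel = np.empty(p, dtype=int)
    relabel[order] = np.arange(1, p + 1)
    return ClusterAssignment(list(cell_ids), relabel[raw])


def cluster_cells(c: EdgeProfileMatrix, k: int = 30, mu: float = 0.5,
                  iters_max: int = 20, tol: float = 1e-6,
                  n_clusters: Optional[int] = None, seed: int = 0,
                  i_max: int = 15, rule: str = "smaller_value",
                  normalized: bool = False,
                  ) -> Tuple[ClusterAssignment, FusedAffinity, EmbeddingSet]:
    """End-to-end ensemble clustering from edge profiles to labels."""
    emb = embed_views(c, seed=seed)
    k_eff = min(k, emb.pca.shape[0] - 1)
    kernels = [local_scaling_kernel(v, k_eff, mu)[1:] for v in emb.views()]
    E, n_iter = fuse_views(kernels, iters_max, tol)
    if n_clusters is None:
        p, lam, gaps = eigengap_cluster_count(E, i_max, rule, normalized)
    else:
        p = int(n_clusters)
        _, lam, gaps = eigengap_cluster_count(E, i_max, rule, normalized)
        logger.info("cluster count overridden by user: p=%d", p)
    labels = spectral_cluster(E, p, seed, list(c.cell_ids),
                              normalized=normalized)
    fused = FusedAffinity(E, list(c.cell_ids), lam, gaps, p, n_iter)
    return labels, fused, emb
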