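"""Gene co-expression network from significant, hard-thresholded Pearson
correlations.

The network keeps a gene pair when (a) the two-sided correlation test is
significant at ``alpha`` and (b) the absolute correlation strictly
exceeds a hard threshold ``b0``. ``b0`` can be supplied, or selected as
the smallest threshold whose unweighted degree distribution fits a
scale-free law (log-log linear fit), the WGCNA hard-threshold criterion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .containers import GeneExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_GRID = tuple(np.round(np.arange(0.10, 0.951, 0.05), 2))


def pearson_matrix(E: GeneExpressionMatrix) -> Tuple[np.ndarray, np.ndarray]:
    """All-pairs Pearson correlations and two-sided p-values.

    p-values come from the t statistic ``r * sqrt((n-2)/(1-r^2))`` with
    ``n - 2`` degrees of freedom. Genes with zero variance across cells
    get correlation 0 and p-value 1 against every other gene.
    """
    n = E.n_cells
    if n < 3:
        raise ValidationError("pearson_matrix needs at least 3 cells")
    v = E.values
    sd = v.std(axis=1)
    flat = sd == 0
    if flat.any():
        logger.info("pearson_matrix: %d zero-variance genes", flat.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(v)
    R = np.nan_to_num(R, nan=0.0)
    np.clip(R, -1.0, 1.0, out=R)
    with np.errstate(divide="ignore"):
        t = R * np.sqrt((n - 2) / np.maximum(1.0 - R ** 2, 1e-300))
    P = 2.0 * scipy.stats.t.sf(np.abs(t), df=n - 2)
    P[np.abs(R) >= 1.0] = 0.0
    P[flat, :] = 1.0
    P[:, flat] = 1.0
    R[flat, :] = 0.0
    R[:, flat] = 0.0
    np.fill_diagonal(R, 1.0)
    np.fill_diagonal(P, 0.0)
    return R, P


def significance_filter(R: np.ndarray, P: np.ndarray, alpha: float = 0.01,
                        bh_correct: bool = False) -> np.ndarray:
    """Zero non-significant correlations, then take absolute values.

    Returns ``B0 = |R|`` masked at ``p >= alpha`` with a zero diagonal
    (self-correlations never form edges). ``bh_correct`` applies
    Benjamini-Hochberg over the upper triangle before masking.
    """
    if R.shape != P.shape:
        raise ValidationError("R and P must be conformable")
    P = P.copy()
    if bh_correct:
        iu = np.triu_indices_from(P, k=1)
        adj = multipletests(P[iu], method="fdr_bh")[1]
        P[iu] = adj
        P.T[iu] = adj
    B0 = np.where(P < alpha, np.abs(R), 0.0)
    np.fill_diagonal(B0, 0.0)
    return B0


def _scale_free_fit(degrees: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the log-log degree-distribution fit (WGCNA style).

    Degrees are split into ``n_bins`` equal-width bins; each occupied bin
    contributes its mean degree and its occupancy fraction, and
    ``log10 p(k)`` is regressed on ``log10 k`` over those bins.
    Degree-0 nodes are excluded. The sign of the fitted slope is folded
    in so only decreasing distributions score positively. NaN when fewer
    than 3 occupied bins remain.
    """
    k = degrees[degrees > 0].astype(float)
    if k.size < 3 or np.ptp(k) == 0:
        return float("nan")
    hist, edges = np.histogram(k, bins=n_bins)
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    ok = hist > 0
    if ok.sum() < 3:
        return float("nan")
    mean_k = np.array([k[which == b].mean() for b in range(n_bins) if ok[b]])
    p_k = hist[ok] / k.size
    slope, _, r, _, _ = scipy.stats.linregress(np.log10(mean_k),
                                               np.log10(p_k))
    return float(-np.sign(slope) * r ** 2)


def choose_hard_threshold(B0: np.ndarray,
                          candidate_grid: Sequence[float] = DEFAULT_GRID,
                          r2_target: float = 0.80,
                          min_connected_fraction: float = 0.5,
                          ) -> Tuple[float, pd.DataFrame]:
    """Pick the smallest threshold whose thresholded graph looks scale-free.

    For each candidate the unweighted graph ``{b_ij > tau}`` is formed and
    the signed R^2 of its log-log degree fit recorded; the chosen ``b0``
    is the smallest candidate reaching ``r2_target``, falling back to the
    argmax when none does. Candidates that disconnect more than
    ``1 - min_connected_fraction`` of the genes are treated as degenerate
    (a fragmented remnant can fit a power law spuriously well), as are
    candidates whose degree distribution spans too few bins to fit.
    """
    grid = list(candidate_grid)
    if not grid:
        raise ValidationError("empty candidate grid")
    n_genes = B0.shape[0]
    rows = []
    for tau in grid:
        adj = B0 > tau
        np.fill_diagonal(adj, False)
        deg = adj.sum(axis=0)
        n_edges = int(adj.sum()) // 2
        n_connected = int((deg > 0).sum())
        if n_edges and n_connected >= min_connected_fraction * n_genes:
            fit = _scale_free_fit(deg)
        else:
            fit = float("nan")
        rows.append({"threshold": tau, "n_edges": n_edges,
                     "n_connected": n_connected, "scale_free_r2": fit})
    diag = pd.DataFrame(rows)
    if (diag["n_edges"] == 0).all():
        raise ValidationError(
            "no edges at any candidate threshold; lower the grid")
    ok = diag["scale_free_r2"] >= r2_target
    if ok.any():
        b0 = float(diag.loc[ok, "threshold"].iloc[0])
    else:
        usable = diag.dropna(subset=["scale_free_r2"])
        if usable.empty:
            # too few connected genes to judge scale-freeness anywhere:
            # keep the densest informative graph
            b0 = float(diag.loc[diag["n_edges"] > 0, "threshold"].iloc[0])
        else:
            b0 = float(
                usable.loc[usable["scale_free_r2"].idxmax(), "threshold"])
    logger.info("hard threshold b0=%.2f selected", b0)
    return b0, diag


@dataclass
class CoexpressionGraph:
    """Undirected gene graph of significant, thresholded correlations."""

    graph: nx.Graph
    b0: float
    diagnostics: Optional[pd.DataFrame] = None
    threshold_source: str = "auto"
    alpha: float = 0.01

    @property
    def genes(self) -> list:
        return sorted(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_list(self) -> list:
        return sorted(tuple(sorted(e)) for e in self.graph.edges)


def build_coexpression_graph(B0: np.ndarray, b0: float, gene_ids: Sequence,
                             R: Optional[np.ndarray] = None,
                             P: Optional[np.ndarray] = None,
                             diagnostics: Optional[pd.DataFrame] = None,
                             threshold_source: str = "auto",
                             ) -> CoexpressionGraph:
    """Edges where ``b_ij > b0`` strictly; isolated genes are not nodes."""
    if not 0.0 <= b0 < 1.0:
        raise ValidationError(f"b0 must lie in [0, 1), got {b0}")
    g = nx.Graph()
    ii, jj = np.nonzero(np.triu(B0, k=1) > b0)
    for i, j in zip(ii, jj):
        attrs = {"abs_r": float(B0[i, j])}
        if R is not None:
            attrs["r"] = float(R[i, j])
        if P is not None:
            attrs["p"] = float(P[i, j])
        g.add_edge(gene_ids[i], gene_ids[j], **attrs)
    if g.number_of_edges() == 0:
        raise ValidationError(f"no co-expression edges at b0={b0}")
    logger.info("co-expression graph: %d nodes, %d edges",
                g.number_of_nodes(), g.number_of_edges())
    return CoexpressionGraph(g, b0, diagnostics, threshold_source)


def coexpression_network(E: GeneExpressionMatrix, alpha: float = 0.01,
                         b0: Optional[float] = None,
                         candidate_grid: Sequence[float] = DEFAULT_GRID,
                         r2_target: float = 0.80,
                         bh_correct: bool = False) -> CoexpressionGraph:
    """Full route: correlations -> significance mask -> threshold -> graph."""
    R, P = pearson_matrix(E)
    B0 = significance_filter(R, P, alpha, bh_correct)
    if b0 is None:
        b0, diag = choose_hard_threshold(B0, candidate_grid, r2_target)
        source = "auto"
    else:
        diag, source = None, "user"
    out = build_coexpression_graph(B0, b0, E.gene_ids, R, P, diag, source)
    out.alpha = alpha
    return out
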