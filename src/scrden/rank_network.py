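"""Gene rank differential expression network.

Expression is replaced by within-cell ranks (1 = lowest expressed gene in
that cell), each co-expression edge becomes a per-cell rank-difference
profile, profiles are min-max normalised per cell and then filtered to
the highest-CV gene pairs. Ranks are far more stable than raw expression
under dropout and depth differences, which is the point of the whole
construction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np
import pandas as pd

from .containers import GeneExpressionMatrix, ValidationError
from .coexpression import CoexpressionGraph

logger = logging.getLogger(__name__)


@dataclass
class RankMatrix:
    """Within-cell ordinal gene ranks; every column is a permutation of 1..m."""

    ranks: np.ndarray  # genes x cells, int
    gene_ids: list
    cell_ids: list
    tie_policy: str = "ordinal"


@dataclass
class EdgeProfileMatrix:
    """Gene-pair x cell rank-difference profiles.

    ``edges[i]`` is the oriented pair ``(g_k, g_l)`` with ``g_k`` the gene
    of smaller index in the rank matrix; ``values[i, t]`` is
    ``rank(g_k, t) - rank(g_l, t)`` (raw) or its per-cell min-max
    normalisation.
    """

    edges: List[Tuple[str, str]]
    values: np.ndarray  # edges x cells
    cell_ids: list
    normalization: str = "raw"  # {"raw", "minmax"}
    cv: np.ndarray | None = None

    @property
    def n_edges(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def edge_labels(self) -> list:
        return [f"{a}|{b}" for a, b in self.edges]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.edge_labels(),
                            columns=self.cell_ids)


def rank_within_cells(E: GeneExpressionMatrix) -> RankMatrix:
    """Rank genes ascending within each cell (ordinal tie-break).

    Ties are broken by gene index, so every column is exactly a
    permutation of ``1..m`` — ranking is then invariant under any
    strictly monotone transform of a cell's values.
    """
    order = np.argsort(E.values, axis=0, kind="stable")
    ranks = np.empty_like(order)
    m = E.n_genes
    rows = np.arange(m)[:, None]
    np.put_along_axis(ranks, order, rows + 1, axis=0)
    return RankMatrix(ranks, list(E.gene_ids), list(E.cell_ids))


def build_edge_profiles(C0: RankMatrix,
                        B: CoexpressionGraph) -> EdgeProfileMatrix:
    """One profile row per co-expression edge: per-cell rank differences.

    Orientation is fixed as (smaller gene index, larger gene index) in
    ``C0``'s gene ordering; swapping it would negate the row.
    """
    pos = {g: i for i, g in enumerate(C0.gene_ids)}
    edges = []
    for a, b in B.graph.edges:
        for g in (a, b):
            if g not in pos:
                raise ValidationError(
                    f"edge gene {g!r} missing from the rank matrix")
        i, j = pos[a], pos[b]
        edges.append((i, j) if i < j else (j, i))
    edges.sort()
    idx = np.array(edges, dtype=int)
    values = (C0.ranks[idx[:, 0]] - C0.ranks[idx[:, 1]]).astype(float)
    named = [(C0.gene_ids[i], C0.gene_ids[j]) for i, j in edges]
    return EdgeProfileMatrix(named, values, list(C0.cell_ids), "raw")


def minmax_normalize(c: EdgeProfileMatrix,
                     degenerate_value: float = 0.0) -> EdgeProfileMatrix:
    """Min-max scale each cell's column of rank differences to [0, 1].

    A constant column (max = min) maps to ``degenerate_value``.
    """
    if c.normalization != "raw":
        raise ValidationError("profiles already normalized")
    v = c.values
    lo = v.min(axis=0, keepdims=True)
    rng = v.max(axis=0, keepdims=True) - lo
    degenerate = rng == 0
    safe = np.where(degenerate, 1.0, rng)
    out = (v - lo) / safe
    if degenerate.any():
        out[:, degenerate[0]] = degenerate_value
        logger.info("minmax_normalize: %d degenerate cells",
                    int(degenerate.sum()))
    return EdgeProfileMatrix(list(c.edges), out, list(c.cell_ids), "minmax")


def filter_top_cv(c: EdgeProfileMatrix, top_fraction: float = 0.01,
                  min_keep: int = 1) -> EdgeProfileMatrix:
    """Keep the gene pairs with the largest coefficient of variation.

    CV = sd / mean per edge row across cells; rows with zero mean are
    dropped first. ``ceil(top_fraction * n_rows)`` rows are retained
    (never fewer than ``min_keep``), ties broken by row order, and the
    surviving rows keep their original relative order.
    """
    mean = c.values.mean(axis=1)
    nonzero = mean != 0
    if not nonzero.any():
        raise ValidationError("all edge profiles have zero mean")
    idx = np.flatnonzero(nonzero)
    cv = c.values[idx].std(axis=1) / mean[idx]
    n_keep = min(len(idx), max(math.ceil(top_fraction * len(idx)), min_keep))
    top = np.sort(idx[np.argsort(-cv, kind="stable")[:n_keep]])
    cv_by_row = dict(zip(idx, cv))
    out = EdgeProfileMatrix(
        [c.edges[i] for i in top], c.values[top].copy(), list(c.cell_ids),
        c.normalization, np.array([cv_by_row[i] for i in top]))
    logger.info("filter_top_cv: kept %d of %d edges", out.n_edges, c.n_edges)
    return out
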