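"""Core in-memory containers shared across the pipeline.

The central object is :class:`GeneExpressionMatrix`, a genes x cells
non-negative matrix with gene/cell identifiers and optional per-cell
metadata (collection time, stage label, batch).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


def _check_unique(ids: Sequence[str], what: str) -> list:
    ids = list(ids)
    if len(set(ids)) != len(ids):
        seen, dup = set(), []
        for i in ids:
            if i in seen:
                dup.append(i)
            seen.add(i)
        raise ValidationError(f"duplicate {what} identifiers: {dup[:5]}")
    return ids


@dataclass
class GeneExpressionMatrix:
    """Genes x cells expression matrix with identifiers.

    Parameters
    ----------
    values
        Non-negative reals, shape ``(n_genes, n_cells)``. Missing entries
        must be resolved (to zero) before construction.
    gene_ids, cell_ids
        Unique identifiers matching the matrix dimensions.
    cell_meta
        Optional table indexed by ``cell_id`` with columns such as
        ``collection_time``, ``stage_label`` and ``batch``.
    """

    values: np.ndarray
    gene_ids: list = field(default_factory=list)
    cell_ids: list = field(default_factory=list)
    cell_meta: Optional[pd.DataFrame] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("expression matrix must be 2-dimensional")
        if np.isnan(self.values).any():
            n = int(np.isnan(self.values).sum())
            logger.info("replacing %d missing entries with 0", n)
            self.values = np.nan_to_num(self.values, nan=0.0)
        if (self.values < 0).any():
            raise ValidationError("expression matrix has negative entries")
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.cell_ids = _check_unique(self.cell_ids, "cell")
        m, n = self.values.shape
        if len(self.gene_ids) != m:
            raise ValidationError(
                f"{len(self.gene_ids)} gene ids for {m} matrix rows")
        if len(self.cell_ids) != n:
            raise ValidationError(
                f"{len(self.cell_ids)} cell ids for {n} matrix columns")
        if self.cell_meta is not None:
            missing = set(self.cell_ids) - set(self.cell_meta.index)
            if missing:
                raise ValidationError(
                    f"cell_meta lacks rows for {len(missing)} cells")
            self.cell_meta = self.cell_meta.loc[self.cell_ids]

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in matrix") from None

    def subset_genes(self, keep: Sequence) -> "GeneExpressionMatrix":
        """Return a copy restricted to ``keep`` (gene ids or boolean mask)."""
        keep = list(keep)
        if keep and isinstance(keep[0], (bool, np.bool_)):
            idx = np.flatnonzero(keep)
        else:
            pos = {g: i for i, g in enumerate(self.gene_ids)}
            idx = np.array([pos[g] for g in keep], dtype=int)
        return GeneExpressionMatrix(
            self.values[idx].copy(),
            [self.gene_ids[i] for i in idx],
            list(self.cell_ids),
            self.cell_meta,
        )

    def subset_cells(self, keep: Sequence) -> "GeneExpressionMatrix":
        keep = list(keep)
        if keep and isinstance(keep[0], (bool, np.bool_)):
            idx = np.flatnonzero(keep)
        else:
            pos = {c: i for i, c in enumerate(self.cell_ids)}
            idx = np.array([pos[c] for c in keep], dtype=int)
        meta = None
        if self.cell_meta is not None:
            meta = self.cell_meta.iloc[idx]
        return GeneExpressionMatrix(
            self.values[:, idx].copy(),
            list(self.gene_ids),
            [self.cell_ids[i] for i in idx],
            meta,
        )

    def copy(self) -> "GeneExpressionMatrix":
        meta = None if self.cell_meta is None else self.cell_meta.copy()
        return GeneExpressionMatrix(
            self.values.copy(), list(self.gene_ids), list(self.cell_ids), meta)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids,
                            columns=self.cell_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   cell_meta: Optional[pd.DataFrame] = None):
        return cls(df.to_numpy(dtype=float), list(df.index.astype(str)),
                   list(df.columns.astype(str)), cell_meta)
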