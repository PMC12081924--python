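"""Readers and writers for the matrix and table formats the pipeline touches.

Supported expression inputs:

* dense CSV/TSV with gene ids in the first column and cell ids in the
  header (rows = genes by default; ``cells_as_rows`` transposes);
* MatrixMarket coordinate triplets in the 10x layout — ``matrix.mtx``
  next to ``features.tsv`` (or ``genes.tsv``) and ``barcodes.tsv``.

Networks are exchanged as tab-separated edge lists with lexicographically
ordered gene pairs.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import GeneExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)

_FEATURE_NAMES = ("features.tsv", "genes.tsv", "features.txt", "genes.txt")
_BARCODE_NAMES = ("barcodes.tsv", "barcodes.txt")


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".txt", ".tab") else ","


def read_expression(path, fmt: str = "dense", cells_as_rows: bool = False,
                    cell_meta: Optional[pd.DataFrame] = None,
                    ) -> GeneExpressionMatrix:
    """Load an expression matrix as genes x cells.

    Parameters
    ----------
    path
        Dense table file, or for ``fmt="mtx"`` either the ``.mtx`` file or
        the directory holding the 10x triplet layout.
    fmt
        ``"dense"`` or ``"mtx"``.
    cells_as_rows
        Dense input only: declare that rows are cells, so the table is
        transposed after reading.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt in ("dense", "csv", "tsv"):
        return _read_dense(path, cells_as_rows, cell_meta)
    if fmt in ("mtx", "mtx_triplet", "10x"):
        return _read_mtx(path, cell_meta)
    raise ValueError(f"unknown format {fmt!r}")


def _read_dense(path: Path, cells_as_rows: bool,
                cell_meta: Optional[pd.DataFrame]) -> GeneExpressionMatrix:
    try:
        df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    except pd.errors.ParserError as exc:
        raise ValidationError(f"malformed dense matrix {path}: {exc}") from exc
    non_numeric = df.columns[
        [not np.issubdtype(dt, np.number) for dt in df.dtypes]]
    if len(non_numeric):
        raise ValidationError(
            f"non-numeric columns in {path}: {list(non_numeric)[:5]}")
    if cells_as_rows:
        df = df.T
        logger.info("dense input declared cells-as-rows; transposed")
    else:
        logger.info("dense input read as genes x cells")
    n_missing = int(df.isna().sum().sum())
    if n_missing:
        logger.info("%s: %d missing entries set to 0", path, n_missing)
        df = df.fillna(0.0)
    return GeneExpressionMatrix.from_frame(df, cell_meta)


def _find_companion(base: Path, names) -> Path:
    for n in names:
        for cand in (base / n, base / (n + ".gz")):
            if cand.exists():
                return cand
    raise FileNotFoundError(
        f"no companion file among {names} next to {base}")


def _read_mtx(path: Path, cell_meta) -> GeneExpressionMatrix:
    if path.is_dir():
        mtx = None
        for cand in ("matrix.mtx", "matrix.mtx.gz"):
            if (path / cand).exists():
                mtx = path / cand
                break
        if mtx is None:
            raise FileNotFoundError(f"no matrix.mtx under {path}")
        base = path
    else:
        mtx, base = path, path.parent
    try:
        mat = scipy.io.mmread(mtx)
    except ValueError as exc:
        raise ValidationError(f"malformed MatrixMarket file {mtx}: {exc}") from exc
    mat = scipy.sparse.coo_matrix(mat)
    features = _find_companion(base, _FEATURE_NAMES)
    barcodes = _find_companion(base, _BARCODE_NAMES)
    genes = pd.read_csv(features, sep="\t", header=None).iloc[:, 0].astype(str)
    cells = pd.read_csv(barcodes, sep="\t", header=None).iloc[:, 0].astype(str)
    if mat.shape[0] != len(genes) or mat.shape[1] != len(cells):
        raise ValidationError(
            f"matrix shape {mat.shape} does not match "
            f"{len(genes)} features x {len(cells)} barcodes")
    logger.info("mtx input %s: %d stored entries", mtx, mat.nnz)
    return GeneExpressionMatrix(
        np.asarray(mat.todense(), dtype=float), list(genes), list(cells),
        cell_meta)


def write_expression(X: GeneExpressionMatrix, path, fmt: str = "dense") -> None:
    """Write a matrix in either supported format (directory for ``mtx``)."""
    path = Path(path)
    if fmt in ("dense", "csv", "tsv"):
        X.to_frame().to_csv(path, sep=_sep_for(path))
        return
    if fmt in ("mtx", "mtx_triplet", "10x"):
        path.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(str(path / "matrix.mtx"),
                         scipy.sparse.coo_matrix(X.values))
        (path / "features.tsv").write_text(
            "".join(f"{g}\n" for g in X.gene_ids))
        (path / "barcodes.tsv").write_text(
            "".join(f"{c}\n" for c in X.cell_ids))
        return
    raise ValueError(f"unknown format {fmt!r}")


def write_network(graph: nx.Graph, path, weight_attr: str = "weight") -> None:
    """Write an undirected weighted gene graph as a TSV edge list.

    Pairs are ordered lexicographically within each row and rows are
    sorted, so output is byte-reproducible; 17 significant digits keep the
    round-trip exact.
    """
    rows = []
    for u, v, data in graph.edges(data=True):
        a, b = sorted((str(u), str(v)))
        rows.append((a, b, float(data.get(weight_attr, 1.0))))
    rows.sort()
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tweight\n")
        for a, b, w in rows:
            fh.write(f"{a}\t{b}\t{w:.17g}\n")


def read_network(path, weight_attr: str = "weight") -> nx.Graph:
    g = nx.Graph()
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    for a, b, w in df.itertuples(index=False):
        g.add_edge(str(a), str(b), **{weight_attr: float(w)})
    return g
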