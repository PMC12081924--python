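"""Expression-matrix preprocessing: gene screening, outlier smoothing,
log transform and feature-gene selection.

The four steps run in order:

1. name-based and prevalence screening (mitochondrial / ribosomal /
   spike-in genes out; keep genes expressed in more than a minimum
   fraction of cells);
2. per-gene winsorisation to ``mean +/- 4 sd``;
3. ``log2(x + 1)`` so zeros stay zero;
4. selection of high intrinsic-entropy genes with mean log expression
   above a user threshold ``I``.

The intrinsic score used in step 4 is the variance of the gene's log
expression across cells. Genes swept by regulation — broad monotone
ramps, bimodal on/off switches, programmes confined to a subpopulation —
fluctuate far beyond the tight technical spread of a constitutively
expressed gene, so the high-variance tail above the mean floor ``I`` is
enriched for regulated rather than purely technical variation. Histogram
entropy (at a pooled bandwidth) is reported per gene as a diagnostic.
"""

from __future__ import annotations

import logging
import re
from typing import Iterable, Sequence, Tuple

import numpy as np
import pandas as pd

from .containers import GeneExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)

#: shipped name-screen patterns: mouse and human mitochondrial and
#: ribosomal prefixes plus ERCC spike-ins
DEFAULT_SCREEN_PATTERNS = (
    r"^mt-", r"^MT-", r"^Rps", r"^Rpl", r"^RPS", r"^RPL", r"^ERCC-",
)


def screen_genes(X: GeneExpressionMatrix,
                 blocklists: Sequence[Iterable[str]] = (),
                 expression_fraction_min: float = 0.10,
                 name_patterns: Sequence[str] = DEFAULT_SCREEN_PATTERNS,
                 ) -> Tuple[GeneExpressionMatrix, pd.DataFrame]:
    """Drop blocklisted/name-matched genes and rarely expressed genes.

    A gene survives the prevalence filter only if its count is strictly
    positive in strictly more than ``expression_fraction_min`` of cells.
    Returns the reduced matrix and a per-gene screening table with reason
    codes ``screened_name`` / ``low_fraction`` / ``kept``.
    """
    blocked = set()
    for bl in blocklists:
        blocked.update(bl)
    regexes = [re.compile(p) for p in name_patterns]
    frac = (X.values > 0).mean(axis=1)
    reasons = []
    for g, f in zip(X.gene_ids, frac):
        if g in blocked or any(r.search(g) for r in regexes):
            reasons.append("screened_name")
        elif f <= expression_fraction_min:
            reasons.append("low_fraction")
        else:
            reasons.append("kept")
    report = pd.DataFrame({
        "gene_id": X.gene_ids,
        "fraction_cells_expressed": frac,
        "reason": reasons,
    }).set_index("gene_id")
    keep = [g for g, r in zip(X.gene_ids, reasons) if r == "kept"]
    if not keep:
        raise ValidationError("screening removed every gene")
    logger.info("screen_genes: kept %d of %d genes", len(keep), X.n_genes)
    return X.subset_genes(keep), report


def winsorize_outliers(X: GeneExpressionMatrix,
                       sigma_clip: float = 4.0) -> GeneExpressionMatrix:
    """Clip each gene to ``mean +/- sigma_clip * sd`` (then floor at 0).

    Bounds come from the gene's own mean and standard deviation across
    cells before clipping; a constant gene (sd = 0) is left unchanged.
    """
    v = X.values
    mu = v.mean(axis=1, keepdims=True)
    sd = v.std(axis=1, keepdims=True)
    lo = np.maximum(mu - sigma_clip * sd, 0.0)
    hi = mu + sigma_clip * sd
    out = X.copy()
    out.values = np.clip(v, lo, hi)
    return out


def log_transform(X: GeneExpressionMatrix) -> GeneExpressionMatrix:
    """Elementwise ``log2(x + 1)``; zeros map to zeros."""
    out = X.copy()
    out.values = np.log2(X.values + 1.0)
    return out


def _global_bin_width(X: np.ndarray) -> float:
    """Freedman-Diaconis bin width pooled over all positive log values.

    One shared width keeps the entropy scale-sensitive: a gene whose
    expression sweeps a wide range occupies more bins (higher entropy)
    than a tight unimodal gene, which per-gene binning would hide.
    """
    pos = X[X > 0]
    if pos.size < 2:
        return 1.0
    iqr = float(np.subtract(*np.percentile(pos, [75, 25])))
    width = 2.0 * iqr * pos.size ** (-1.0 / 3.0)
    return width if width > 0 else 1.0


def _gene_entropy(values: np.ndarray, bin_width: float) -> float:
    """Shannon entropy (nats) of one gene's expression histogram.

    Zeros form their own bin; positive values are binned at the shared
    ``bin_width`` over the gene's own range.
    """
    pos = values[values > 0]
    counts = [float((values == 0).sum())]
    if pos.size:
        n_bins = max(int(np.ceil(np.ptp(pos) / bin_width)), 1)
        hist, _ = np.histogram(pos, bins=n_bins)
        counts.extend(hist.astype(float))
    p = np.array(counts)
    p = p[p > 0] / p.sum()
    return float(-(p * np.log(p)).sum())


def select_feature_genes(X: GeneExpressionMatrix,
                         intrinsic_mean_min: float = 1.0,
                         cutoff_quantile: float = 0.90,
                         min_genes: int = 10,
                         ) -> Tuple[GeneExpressionMatrix, pd.DataFrame]:
    """Keep high intrinsic-entropy genes with mean log expression > ``I``.

    ``X`` must already be log-transformed. The intrinsic score of a gene
    is the variance of its log expression across cells: genes swept by
    regulation (broad ramps, on/off switches, programmes active in a
    subpopulation) fluctuate far beyond the tight technical spread of a
    constitutively expressed gene, and a constant gene scores exactly 0.
    Genes above the ``cutoff_quantile`` of scores AND with mean above
    ``intrinsic_mean_min`` are retained. The histogram entropy of each
    gene (shared Freedman-Diaconis bandwidth, zeros as their own bin) is
    reported alongside as a diagnostic.
    """
    means = X.values.mean(axis=1)
    score = X.values.var(axis=1)
    width = _global_bin_width(X.values)
    entropies = np.array([_gene_entropy(row, width) for row in X.values])
    cutoff = np.quantile(score, cutoff_quantile)
    kept = (score > cutoff) & (means > intrinsic_mean_min)
    reasons = np.where(kept, "kept", "low_intrinsic")
    report = pd.DataFrame({
        "gene_id": X.gene_ids,
        "mean_log_expression": means,
        "entropy": entropies,
        "intrinsic_score": score,
        "kept": kept,
        "reason": reasons,
    }).set_index("gene_id")
    n_kept = int(kept.sum())
    if n_kept < min_genes:
        raise ValidationError(
            f"only {n_kept} feature genes survive; lower intrinsic_mean_min "
            f"(I={intrinsic_mean_min}) or cutoff_quantile ({cutoff_quantile})")
    logger.info("select_feature_genes: kept %d of %d genes", n_kept, X.n_genes)
    return X.subset_genes(list(kept)), report


def preprocess(X: GeneExpressionMatrix, *,
               blocklists: Sequence[Iterable[str]] = (),
               expression_fraction_min: float = 0.10,
               sigma_clip: float = 4.0,
               intrinsic_mean_min: float = 1.0,
               cutoff_quantile: float = 0.90,
               name_patterns: Sequence[str] = DEFAULT_SCREEN_PATTERNS,
               ) -> Tuple[GeneExpressionMatrix, GeneExpressionMatrix,
                          pd.DataFrame]:
    """Run the full four-step preprocessing.

    Returns ``(E, X_log_all, qc)``: the feature-selected matrix, the
    log-transformed matrix over all screened genes (used later for marker
    testing), and a QC table over every input gene whose reason codes
    partition the input panel.
    """
    screened, screen_report = screen_genes(
        X, blocklists, expression_fraction_min, name_patterns)
    smooth = winsorize_outliers(screened, sigma_clip)
    logged = log_transform(smooth)
    E, feat_report = select_feature_genes(
        logged, intrinsic_mean_min, cutoff_quantile)
    qc = screen_report.copy()
    qc["mean"] = X.values.mean(axis=1)
    qc["sd"] = X.values.std(axis=1)
    qc["n_winsorized_entries"] = 0
    qc.loc[list(screened.gene_ids), "n_winsorized_entries"] = (
        screened.values != smooth.values).sum(axis=1)
    for col in ("mean_log_expression", "intrinsic_score"):
        qc[col] = np.nan
        qc.loc[feat_report.index, col] = feat_report[col]
    qc.loc[feat_report.index, "reason"] = feat_report["reason"]
    qc["kept"] = qc["reason"] == "kept"
    return E, logged, qc
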