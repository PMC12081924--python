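"""End-to-end orchestration: raw counts to clusters, pseudotime and
stage-network dynamics, plus the noise-robustness protocol."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import coexpression, dynamic_network, ensemble_cluster, metrics, \
    preprocess, rank_network, trajectory
from .config import PipelineConfig
from .containers import GeneExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Everything one run produces, stage by stage."""

    config: PipelineConfig
    E: GeneExpressionMatrix
    X_log: GeneExpressionMatrix
    qc: pd.DataFrame
    graph: coexpression.CoexpressionGraph
    profiles: rank_network.EdgeProfileMatrix
    embeddings: ensemble_cluster.EmbeddingSet
    fused: ensemble_cluster.FusedAffinity
    labels: ensemble_cluster.ClusterAssignment
    model: trajectory.TrajectoryModel

    def cell_ordering(self) -> list:
        return self.model.cell_ordering()


def infer_from_log(X_log: GeneExpressionMatrix, config: PipelineConfig,
                   start_markers: Optional[Sequence[str]] = None,
                   qc: Optional[pd.DataFrame] = None) -> PipelineResult:
    """Run network construction, clustering and pseudotime from a
    preprocessed (screened + winsorised + log) matrix.

    Feature selection happens here so the same entry point serves the
    perturbation protocol, which injects noise into the log matrix.
    """
    E, feat_report = preprocess.select_feature_genes(
        X_log, config.intrinsic_mean_min, config.intrinsic_cutoff_quantile)
    graph = coexpression.coexpression_network(
        E, alpha=config.pearson_alpha, b0=config.hard_threshold_b0,
        r2_target=config.scale_free_r2, bh_correct=config.pearson_bh_correct)
    C0 = rank_network.rank_within_cells(E)
    raw_profiles = rank_network.build_edge_profiles(C0, graph)
    normed = rank_network.minmax_normalize(raw_profiles)
    profiles = rank_network.filter_top_cv(
        normed, config.cv_top_fraction, config.min_cv_edges)
    labels, fused, emb = ensemble_cluster.cluster_cells(
        profiles, k=config.knn_k, mu=config.kernel_mu,
        iters_max=config.snf_iters_max, tol=config.snf_tol,
        n_clusters=config.n_clusters, seed=config.random_seed,
        i_max=config.eigengap_i_max, rule=config.eigengap_rule,
        normalized=config.normalized_laplacian)
    if start_markers:
        start = trajectory.choose_start_cluster(X_log, labels, start_markers)
    else:
        start = 1
        logger.warning("no start markers given; using largest cluster as "
                       "start — supply markers for a meaningful origin")
    model = trajectory.cluster_pseudotime(
        emb.tsne, labels, start, config.pseudotime_mode)
    trajectory.derive_lineage_paths(model)
    if qc is None:
        qc = feat_report
    return PipelineResult(config, E, X_log, qc, graph, profiles, emb,
                          fused, labels, model)


def run_pipeline(X: GeneExpressionMatrix, config: PipelineConfig,
                 start_markers: Optional[Sequence[str]] = None,
                 blocklists: Sequence = ()) -> PipelineResult:
    """Full pipeline from a raw genes x cells count matrix."""
    screened, _ = preprocess.screen_genes(
        X, blocklists, config.expression_fraction_min)
    smooth = preprocess.winsorize_outliers(screened, config.sigma_clip)
    X_log = preprocess.log_transform(smooth)
    return infer_from_log(X_log, config, start_markers)


def robustness_protocol(X: GeneExpressionMatrix, config: PipelineConfig,
                        start_markers: Optional[Sequence[str]] = None,
                        n_replicates: int = 5,
                        noise_levels: Optional[Sequence[float]] = None,
                        ) -> pd.DataFrame:
    """Robust score of the trajectory under Gaussian perturbation.

    The unperturbed pipeline fixes the reference ordering; for each noise
    level k and replicate, per-gene scaled Gaussian noise is added to the
    log matrix, the trajectory is re-inferred and the robust score
    against the reference recorded. Returns a tidy table
    (noise_level, replicate, robust_score).
    """
    if noise_levels is None:
        noise_levels = config.noise_levels
    screened, _ = preprocess.screen_genes(
        X, (), config.expression_fraction_min)
    smooth = preprocess.winsorize_outliers(screened, config.sigma_clip)
    X_log = preprocess.log_transform(smooth)
    reference = infer_from_log(X_log, config, start_markers).cell_ordering()
    rows = []
    for k in noise_levels:
        for rep in range(n_replicates):
            noise_seed = (config.random_seed + 9973 * rep
                          + int(round(1e4 * k))) % (2 ** 31)
            perturbed = metrics.perturb_with_noise(X_log, k, noise_seed)
            try:
                ordering = infer_from_log(
                    perturbed, config, start_markers).cell_ordering()
                score = metrics.robust_score(reference, ordering)
            except ValidationError as exc:
                logger.warning("replicate (k=%s, rep=%d) failed: %s",
                               k, rep, exc)
                score = np.nan
            rows.append({"noise_level": k, "replicate": rep,
                         "robust_score": score})
    return pd.DataFrame(rows)
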