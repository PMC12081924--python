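"""Pipeline configuration: every threshold and hyperparameter in one place."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import yaml

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Thresholds and hyperparameters with their defaults.

    Attributes
    ----------
    expression_fraction_min
        A gene is kept only if expressed (count > 0) in strictly more than
        this fraction of cells.
    sigma_clip
        Per-gene winsorisation half-width in standard deviations; entries
        outside ``mean +/- sigma_clip * sd`` are clipped to the boundary.
    intrinsic_mean_min
        Minimum mean log2 expression (``I``) for a feature gene.
    intrinsic_cutoff_quantile
        Quantile of the residual-entropy score above which a gene counts as
        high intrinsic entropy.
    pearson_alpha
        Raw p-value cut for retaining a gene-gene correlation.
    hard_threshold_b0
        Co-expression hard threshold; ``None`` selects it by scale-free fit.
    cv_top_fraction
        Fraction of edge profiles (by coefficient of variation) retained.
    min_cv_edges
        Floor on the number of retained edge profiles, so small matrices
        still yield a usable feature space.
    knn_k
        Neighbourhood size for the local-scaling kernels.
    kernel_mu
        Bandwidth multiplier of the local-scaling kernel.
    snf_iters_max, snf_tol
        Fusion iteration budget and convergence tolerance.
    n_clusters
        Cluster count; ``None`` selects it by the eigengap rule.
    eigengap_rule
        ``"smaller_value"``: of the top-two eigengaps take the index of the
        smaller gap value; ``"smaller_index"``: take the smaller index.
    edge_display_threshold
        Stage-network edges with weight strictly below this are discarded.
    noise_levels
        Gaussian perturbation scale factors for the robustness protocol.
    """

    expression_fraction_min: float = 0.10
    sigma_clip: float = 4.0
    intrinsic_mean_min: float = 1.0
    intrinsic_cutoff_quantile: float = 0.90
    pearson_alpha: float = 0.01
    pearson_bh_correct: bool = False
    hard_threshold_b0: Optional[float] = None
    scale_free_r2: float = 0.80
    cv_top_fraction: float = 0.01
    min_cv_edges: int = 200
    knn_k: int = 30
    kernel_mu: float = 0.5
    snf_iters_max: int = 20
    snf_tol: float = 1e-6
    n_clusters: Optional[int] = None
    eigengap_rule: str = "smaller_value"
    eigengap_i_max: int = 15
    normalized_laplacian: bool = False
    pseudotime_mode: str = "normalized_distance"
    edge_display_threshold: float = 0.2
    noise_levels: Tuple[float, ...] = (0.05, 0.10, 0.20)
    random_seed: int = 0

    def __post_init__(self):
        for name in ("expression_fraction_min", "cv_top_fraction",
                     "intrinsic_cutoff_quantile"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")
        if self.pseudotime_mode not in ("normalized_distance", "rank"):
            raise ValueError(f"unknown pseudotime_mode {self.pseudotime_mode}")
        if self.eigengap_rule not in ("smaller_value", "smaller_index"):
            raise ValueError(f"unknown eigengap_rule {self.eigengap_rule}")
        logger.info("pipeline seed fixed at %d", self.random_seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["noise_levels"] = list(d["noise_levels"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "noise_levels" in d:
            d = dict(d, noise_levels=tuple(d["noise_levels"]))
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix == ".json":
            return cls.from_dict(json.loads(text))
        return cls.from_dict(yaml.safe_load(text))

    def to_file(self, path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict()))
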