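"""Branching single-cell expression simulator with known ground truth.

Cells carry a latent time ``t ~ Uniform[0, 1]`` and one of ``n_branches``
branch labels; expression before the branch point is branch-independent
(the shared root segment). Gene mean programmes come in five flavours —
ramp-up, ramp-down, switch-like (sigmoidal), branch-specific ramp-up,
housekeeping and pure noise — and counts are drawn negative-binomial with
zero-inflation dropout whose probability decreases with the mean, the
standard caricature of scRNA-seq technical noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .containers import GeneExpressionMatrix, ValidationError

#: default fractions of the gene panel per programme (1-branch data folds
#: the branch-specific share into ramp-up)
MODULE_FRACTIONS = {
    "ramp_up": 0.20,
    "ramp_down": 0.15,
    "switch": 0.15,
    "branch": 0.20,
    "housekeeping": 0.20,
    "noise": 0.10,
}

# Dynamic genes sweep their mean over an amplitude large relative to
# negative-binomial noise, so single dynamic genes are strongly
# time-correlated, as marker genes are in well-powered differentiation
# datasets. Baselines, amplitudes and activation windows vary per gene so
# the gene-gene correlation structure has modules and hubs rather than
# one clique.
_BASE_RANGE = (0.5, 2.0)
_AMP_RANGE = (40.0, 80.0)


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a simulated matrix."""

    true_time: np.ndarray
    branch_label: list
    module_assignment: Dict[str, str]
    params: dict = field(default_factory=dict)

    def frame(self, cell_ids) -> pd.DataFrame:
        return pd.DataFrame({
            "cell_id": list(cell_ids),
            "true_time": self.true_time,
            "branch_label": self.branch_label,
        }).set_index("cell_id")

    def genes_in_module(self, module: str) -> list:
        return [g for g, m in self.module_assignment.items() if m == module]


def _module_counts(n_genes: int, n_branches: int) -> Dict[str, int]:
    frac = dict(MODULE_FRACTIONS)
    if n_branches == 1:
        frac["ramp_up"] += frac.pop("branch")
    counts = {m: int(round(f * n_genes)) for m, f in frac.items()}
    counts["housekeeping"] += n_genes - sum(counts.values())
    return counts


def simulate_branching(n_genes: int = 400, n_cells: int = 300,
                       n_branches: int = 1, dropout_rate: float = 0.1,
                       nb_dispersion: float = 10.0, branch_point: float = 0.4,
                       steepness: float = 10.0, seed: int = 0,
                       ) -> tuple[GeneExpressionMatrix, SyntheticTruth]:
    """Simulate a branching trajectory as a genes x cells count matrix.

    Parameters
    ----------
    n_branches
        Number of terminal branches; 1 gives a linear trajectory.
    dropout_rate
        Maximum zero-inflation probability (attained as the mean -> 0);
        the per-entry probability is ``dropout_rate * exp(-mean / 2)``.
    nb_dispersion
        Negative-binomial size parameter; variance is
        ``mean + mean^2 / nb_dispersion`` (Poisson as it grows large).
    branch_point
        Latent time after which branch-specific programmes diverge.
    steepness
        Slope of the switch-like sigmoid programmes.
    """
    if n_branches < 1:
        raise ValidationError("n_branches must be >= 1")
    if n_cells < 10 * n_branches:
        raise ValidationError("need at least 10 cells per branch")
    if n_genes < 10:
        raise ValidationError("need at least 10 genes")
    rng = np.random.default_rng(seed)

    t = rng.uniform(0.0, 1.0, size=n_cells)
    branch_idx = rng.integers(0, n_branches, size=n_cells)
    branch_label = [f"branch{b + 1}" for b in branch_idx]

    counts = _module_counts(n_genes, n_branches)
    gene_ids, modules = [], []
    for module, c in counts.items():
        for _ in range(c):
            gene_ids.append(f"g{len(gene_ids):04d}")
            modules.append(module)

    mean = np.empty((n_genes, n_cells))
    # branch-specific genes are split evenly over branches
    branch_gene_owner = {}
    owner_cycle = 0

    def _ramp(x, s, e):
        return np.clip((x - s) / (e - s), 0.0, 1.0)

    for gi, module in enumerate(modules):
        base = rng.uniform(*_BASE_RANGE)
        amp = rng.uniform(*_AMP_RANGE)
        if module in ("ramp_up", "ramp_down"):
            s = rng.uniform(0.0, 0.3)
            e = min(s + rng.uniform(0.6, 1.0), 1.0)
            prog = _ramp(t, s, e)
            mean[gi] = base + amp * (prog if module == "ramp_up"
                                     else 1.0 - prog)
        elif module == "switch":
            t0 = rng.uniform(0.2, 0.8)
            mean[gi] = base + amp / (1.0 + np.exp(-steepness * (t - t0)))
        elif module == "branch":
            # fate markers switch on rapidly after commitment: sigmoidal
            # activation anchored to zero at the branch point
            own = owner_cycle % n_branches
            owner_cycle += 1
            branch_gene_owner[gene_ids[gi]] = f"branch{own + 1}"
            t0 = branch_point + rng.uniform(0.05, 0.25)
            prog = np.full(n_cells, base)
            on_branch = (t > branch_point) & (branch_idx == own)
            sig = 1.0 / (1.0 + np.exp(-steepness * (t[on_branch] - t0)))
            sig_bp = 1.0 / (1.0 + np.exp(-steepness * (branch_point - t0)))
            prog[on_branch] += amp * np.clip(
                (sig - sig_bp) / (1.0 - sig_bp), 0.0, 1.0)
            mean[gi] = prog
        elif module == "housekeeping":
            mean[gi] = rng.uniform(2.0, 8.0)
        else:  # noise
            mean[gi] = 0.3

    p = nb_dispersion / (nb_dispersion + mean)
    values = rng.negative_binomial(nb_dispersion, p).astype(float)
    if dropout_rate > 0:
        p_drop = dropout_rate * np.exp(-mean / 2.0)
        values[rng.uniform(size=values.shape) < p_drop] = 0.0

    cell_ids = [f"cell{i:04d}" for i in range(n_cells)]
    meta = pd.DataFrame({
        "collection_time": t,
        "stage_label": [f"{b}" for b in branch_label],
        "batch": "batch1",
    }, index=cell_ids)
    X = GeneExpressionMatrix(values, gene_ids, cell_ids, meta)
    truth = SyntheticTruth(
        true_time=t,
        branch_label=branch_label,
        module_assignment=dict(zip(gene_ids, modules)),
        params={
            "n_genes": n_genes, "n_cells": n_cells,
            "n_branches": n_branches, "dropout_rate": dropout_rate,
            "nb_dispersion": nb_dispersion, "branch_point": branch_point,
            "steepness": steepness, "seed": seed,
            "branch_gene_owner": branch_gene_owner,
        },
    )
    return X, truth


def truth_classes(truth: SyntheticTruth, n_root_bins: int = 2,
                  n_branch_bins: int = 2) -> np.ndarray:
    """Discretise the ground truth into branch x time-bin class labels.

    Cells before the branch point fall into ``n_root_bins`` quantile time
    bins shared across branches; cells after it into ``n_branch_bins``
    quantile bins per branch. Used as the reference partition when scoring
    a clustering with ARI/NMI.
    """
    t = truth.true_time
    bp = truth.params.get("branch_point", 0.4)
    labels = np.empty(len(t), dtype=object)
    root = t <= bp
    if root.any():
        qs = np.quantile(t[root], np.linspace(0, 1, n_root_bins + 1))
        bins = np.clip(np.searchsorted(qs, t[root], side="right") - 1,
                       0, n_root_bins - 1)
        labels[root] = [f"root{b}" for b in bins]
    post = ~root
    if post.any():
        qs = np.quantile(t[post], np.linspace(0, 1, n_branch_bins + 1))
        bins = np.clip(np.searchsorted(qs, t[post], side="right") - 1,
                       0, n_branch_bins - 1)
        for i, b in zip(np.flatnonzero(post), bins):
            labels[i] = f"{truth.branch_label[i]}_{b}"
    return labels
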