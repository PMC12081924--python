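"""Trajectory and clustering evaluation metrics.

* POS — pseudo-temporal ordering score: normalised pairwise agreement
  between an inferred cell ordering and true collection times, in
  [-1, 1] (1 = time-sorted, -1 = reverse-sorted).
* robust score — fraction of concordant cell pairs between two inferred
  orderings (e.g. original vs noise-perturbed data), in [0, 1].
* bubble sort index — 1 minus the normalised inversion count between two
  orderings.
* ARI / NMI for clustering agreement.
* a Gaussian perturbation operator implementing the robustness protocol.
"""

from __future__ import annotations

import logging
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np
import scipy.stats
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

from .containers import GeneExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)


def _times_along(order: Sequence, times: Mapping) -> np.ndarray:
    if len(set(order)) != len(order):
        raise ValidationError("ordering contains duplicate cells")
    try:
        return np.array([float(times[c]) for c in order])
    except KeyError as exc:
        raise ValidationError(f"no collection time for cell {exc}") from exc


def pos_score(order: Sequence, times: Mapping) -> float:
    """Pseudo-temporal ordering score of an inferred cell ordering.

    Sums ``g(i, j) = (T(j) - T(i)) / D`` over all pairs with i placed
    before j (``g = 0`` for equal times). ``D`` is the largest attainable
    positive sum — the pair sum of a time-sorted arrangement — so the
    score is 1 exactly for time-sorted orders and -1 for reverse-sorted
    ones. All-equal times give 0 with a warning.
    """
    t = _times_along(order, times)
    n = len(t)
    if n < 2:
        raise ValidationError("POS needs at least 2 cells")
    # sum_{i<j} (t_j - t_i) telescopes over positions
    pos_idx = np.arange(n)
    numer = float(np.sum((2 * pos_idx - (n - 1)) * t))
    ts = np.sort(t)
    D = float(np.sum((2 * pos_idx - (n - 1)) * ts))
    if D == 0:
        logger.warning("all collection times equal; POS defined as 0")
        return 0.0
    return numer / D


def robust_score(o1: Sequence, o2: Sequence) -> float:
    """Fraction of concordant cell pairs between two orderings.

    Pairs are taken over the union of the two cell sets; a pair is
    concordant (h = 1) when both cells appear in both orderings in the
    same relative order, and discordant (h = 0) otherwise — so cells
    present in only one ordering contribute discordant pairs.
    """
    for o in (o1, o2):
        if len(set(o)) != len(o):
            raise ValidationError("ordering contains duplicate cells")
    s1, s2 = set(o1), set(o2)
    union = s1 | s2
    u = len(union)
    if u < 2:
        raise ValidationError("robust score needs at least 2 distinct cells")
    common = s1 & s2
    pos2 = {c: i for i, c in enumerate(o2)}
    seq = [pos2[c] for c in o1 if c in common]
    concordant = _non_inversions(seq)
    total = u * (u - 1) // 2
    return concordant / total


def _non_inversions(seq: Sequence[int]) -> int:
    """Number of pairs already in increasing order."""
    arr = np.asarray(seq)
    m = len(arr)
    if m < 2:
        return 0
    return m * (m - 1) // 2 - _count_inversions(arr)


def _count_inversions(arr: np.ndarray) -> int:
    """Inversion count via ranks + binary indexed tree, O(n log n)."""
    ranks = scipy.stats.rankdata(arr, method="ordinal").astype(int)
    n = len(ranks)
    tree = np.zeros(n + 1, dtype=np.int64)
    before_and_smaller = 0
    for r in ranks:
        j = r - 1
        while j > 0:  # how many earlier elements have smaller rank
            before_and_smaller += tree[j]
            j -= j & (-j)
        j = r
        while j <= n:
            tree[j] += 1
            j += j & (-j)
    return n * (n - 1) // 2 - int(before_and_smaller)


def bubble_sort_index(o1: Sequence, o2: Sequence) -> float:
    """1 minus the normalised inversion count between two orderings.

    Equals 1 for identical orders and 0 for exact reversal; equivalently
    the fraction of adjacent-swap work bubble sort does NOT need.
    """
    if set(o1) != set(o2) or len(set(o1)) != len(o1) \
            or len(set(o2)) != len(o2):
        raise ValidationError("orderings must cover the same distinct cells")
    n = len(o1)
    if n < 2:
        return 1.0
    pos2 = {c: i for i, c in enumerate(o2)}
    seq = np.array([pos2[c] for c in o1])
    inv = _count_inversions(seq)
    return 1.0 - inv / (n * (n - 1) / 2)


def kendall_tau(o1: Sequence, o2: Sequence) -> float:
    """Kendall rank correlation between two duplicate-free orderings."""
    if set(o1) != set(o2):
        raise ValidationError("orderings must cover the same cells")
    pos2 = {c: i for i, c in enumerate(o2)}
    seq = [pos2[c] for c in o1]
    return float(scipy.stats.kendalltau(np.arange(len(seq)), seq).statistic)


def clustering_agreement(labels_a: Sequence, labels_b: Sequence,
                         ) -> Tuple[float, float]:
    """(ARI, NMI) between two labelings of the same cells."""
    if len(labels_a) != len(labels_b):
        raise ValidationError("labelings cover different numbers of cells")
    a = np.asarray(labels_a).astype(str)
    b = np.asarray(labels_b).astype(str)
    ari = float(adjusted_rand_score(a, b))
    nmi = float(normalized_mutual_info_score(a, b,
                                             average_method="arithmetic"))
    return ari, nmi


def perturb_with_noise(X: GeneExpressionMatrix, k_factor: float,
                       seed: int = 0) -> GeneExpressionMatrix:
    """Add per-gene scaled Gaussian noise (robustness protocol).

    Each entry of gene g receives independent
    ``Normal(0, (k_factor * sd_g)^2)`` noise, with ``sd_g`` the gene's
    standard deviation across cells; results are floored at 0. Intended
    for log-scale matrices so the factor has a uniform meaning.
    """
    if k_factor < 0:
        raise ValidationError("k_factor must be non-negative")
    rng = np.random.default_rng(seed)
    sd = X.values.std(axis=1, keepdims=True)
    noise = rng.normal(0.0, 1.0, size=X.values.shape) * (k_factor * sd)
    out = X.copy()
    out.values = np.maximum(X.values + noise, 0.0)
    return out
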