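"""Independent brute-force oracles used by the test suite.

Every function here re-derives a quantity by direct double loops over the
defining formula, deliberately sharing no code with the package.
"""

import math

import numpy as np


def pearson_oracle(X):
    """All-pairs Pearson correlations by the textbook sum formula."""
    m = X.shape[0]
    R = np.eye(m)
    for i in range(m):
        for j in range(m):
            if i == j:
                continue
            y, z = X[i], X[j]
            ybar, zbar = y.mean(), z.mean()
            num = ((y - ybar) * (z - zbar)).sum()
            den = math.sqrt(((y - ybar) ** 2).sum()) \
                * math.sqrt(((z - zbar) ** 2).sum())
            R[i, j] = num / den if den else 0.0
    return R


def rank_oracle(X):
    """Within-cell ascending ordinal ranks via stable sort per column."""
    m, n = X.shape
    ranks = np.zeros((m, n), dtype=int)
    for t in range(n):
        order = sorted(range(m), key=lambda g: (X[g, t], g))
        for pos, g in enumerate(order):
            ranks[g, t] = pos + 1
    return ranks


def edge_profile_oracle(ranks, edges):
    """Rank-difference rows for oriented (i, j) index pairs."""
    out = np.zeros((len(edges), ranks.shape[1]), dtype=float)
    for r, (i, j) in enumerate(edges):
        for t in range(ranks.shape[1]):
            out[r, t] = ranks[i, t] - ranks[j, t]
    return out


def minmax_oracle(values):
    """Per-column min-max scaling; constant columns map to 0."""
    out = np.zeros_like(values, dtype=float)
    for t in range(values.shape[1]):
        col = values[:, t]
        lo, hi = col.min(), col.max()
        if hi > lo:
            out[:, t] = (col - lo) / (hi - lo)
    return out


def local_kernel_oracle(coords, k, mu):
    """Local-scaling kernels (W, P, S) by explicit double loops."""
    n = len(coords)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            D[i, j] = math.dist(coords[i], coords[j])
    rho = np.zeros(n)
    nbrs = []
    for i in range(n):
        order = sorted((j for j in range(n) if j != i),
                       key=lambda j: (D[i, j], j))
        nbrs.append(order[:k])
        rho[i] = np.mean([D[i, j] for j in order[:k]])
    W = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            eps = (rho[i] + rho[j] + D[i, j]) / 3.0
            W[i, j] = math.exp(-D[i, j] ** 2 / (mu * max(eps, 1e-12)))
    P = np.zeros((n, n))
    for i in range(n):
        offsum = sum(W[i, l] for l in range(n) if l != i)
        for j in range(n):
            P[i, j] = 0.5 if j == i else W[i, j] / (2.0 * offsum)
    S = np.zeros((n, n))
    for i in range(n):
        denom = sum(W[i, l] for l in nbrs[i])
        for j in nbrs[i]:
            S[i, j] = W[i, j] / (2.0 * denom)
    return W, P, S


def stage_weight_oracle(profile_values, edges, gene_order, cell_mask):
    """Symmetrised mean-profile weight matrix over the given cells."""
    m = len(gene_order)
    pos = {g: i for i, g in enumerate(gene_order)}
    H = np.zeros((m, m))
    for r, (a, b) in enumerate(edges):
        if a in pos and b in pos:
            vals = [profile_values[r, t]
                    for t in range(profile_values.shape[1]) if cell_mask[t]]
            H[pos[a], pos[b]] = np.mean(vals)
    return H + H.T


def diversity_oracle(weights, adjacency):
    """Scaled Shannon entropy of incident weights, per node."""
    m = weights.shape[0]
    out = np.zeros(m)
    for i in range(m):
        nbrs = [j for j in range(m) if adjacency[i, j]]
        k = len(nbrs)
        if k <= 1:
            continue
        tot = sum(weights[i, j] for j in nbrs)
        se = 0.0
        for j in nbrs:
            p = weights[i, j] / tot
            if p > 0:
                se -= p * math.log(p)
        out[i] = se / math.log(k)
    return out


def cluster_coeff_oracle(adjacency):
    """CO(i) = 2 TR(i) / (k_i (k_i - 1)) by triple loop."""
    m = adjacency.shape[0]
    out = np.zeros(m)
    for i in range(m):
        nbrs = [j for j in range(m) if adjacency[i, j] and j != i]
        k = len(nbrs)
        if k <= 1:
            continue
        tr = 0
        for a in range(len(nbrs)):
            for b in range(a + 1, len(nbrs)):
                if adjacency[nbrs[a], nbrs[b]]:
                    tr += 1
        out[i] = 2.0 * tr / (k * (k - 1))
    return out


def pos_oracle(order_times):
    """POS by explicit pair enumeration; input = times in inferred order."""
    t = list(order_times)
    n = len(t)
    D = 0.0
    ts = sorted(t)
    for i in range(n - 1):
        for j in range(i + 1, n):
            D += ts[j] - ts[i]
    if D == 0:
        return 0.0
    total = 0.0
    for i in range(n - 1):
        for j in range(i + 1, n):
            if t[i] != t[j]:
                total += (t[j] - t[i]) / D
    return total


def concordance_oracle(o1, o2):
    """Robust score by explicit pair enumeration over the union."""
    union = sorted(set(o1) | set(o2), key=str)
    u = len(union)
    p1 = {c: i for i, c in enumerate(o1)}
    p2 = {c: i for i, c in enumerate(o2)}
    h_sum = 0
    for a in range(u - 1):
        for b in range(a + 1, u):
            i, j = union[a], union[b]
            if i in p1 and j in p1 and i in p2 and j in p2:
                if (p1[i] < p1[j]) == (p2[i] < p2[j]):
                    h_sum += 1
    return h_sum / (u * (u - 1) / 2)


def inversion_oracle(o1, o2):
    """Inversion count between two orders by pair enumeration."""
    p2 = {c: i for i, c in enumerate(o2)}
    seq = [p2[c] for c in o1]
    inv = 0
    for a in range(len(seq) - 1):
        for b in range(a + 1, len(seq)):
            if seq[a] > seq[b]:
                inv += 1
    return inv


def ari_oracle(labels_a, labels_b):
    """Adjusted Rand index from explicit pair counts."""
    n = len(labels_a)
    same_a = same_b = same_both = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            sa = labels_a[i] == labels_a[j]
            sb = labels_b[i] == labels_b[j]
            same_a += sa
            same_b += sb
            same_both += sa and sb
    total = n * (n - 1) / 2
    expected = same_a * same_b / total
    maximum = (same_a + same_b) / 2
    if maximum == expected:
        return 0.0
    return (same_both - expected) / (maximum - expected)
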