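"""Naive, loop-based reference implementations used as independent oracles.

Every function here recomputes a statistic from first principles (explicit
set enumeration, hand rank formulas, exhaustive permutation, per-branch
summation) without touching the package's implementations.
"""

from __future__ import annotations

import itertools
from math import comb, sqrt

import numpy as np


def naive_dice(presence: np.ndarray) -> np.ndarray:
    """Dice similarity by explicit set enumeration over sample indices."""
    g, n = presence.shape
    S = np.zeros((g, g))
    for i in range(g):
        for j in range(g):
            A = {k for k in range(n) if presence[i, k]}
            B = {k for k in range(n) if presence[j, k]}
            if i == j:
                S[i, j] = 1.0
            elif len(A) + len(B) == 0:
                S[i, j] = 0.0
            else:
                S[i, j] = 2 * len(A & B) / (len(A) + len(B))
    return S


def _avg_ranks(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x))
    i = 0
    sorted_x = x[order]
    while i < len(x):
        j = i
        while j + 1 < len(x) and sorted_x[j + 1] == sorted_x[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def naive_spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho as Pearson correlation of average ranks."""
    rx, ry = _avg_ranks(np.asarray(x, float)), _avg_ranks(np.asarray(y, float))
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx @ ry) / sqrt((rx @ rx) * (ry @ ry)))


def naive_kruskal(samples: list[np.ndarray]) -> float:
    """Tie-corrected Kruskal-Wallis H via the hand rank-sum formula."""
    allv = np.concatenate(samples)
    N = len(allv)
    ranks = _avg_ranks(allv)
    H = 0.0
    start = 0
    for s in samples:
        r = ranks[start : start + len(s)]
        H += r.sum() ** 2 / len(s)
        start += len(s)
    H = 12.0 / (N * (N + 1)) * H - 3 * (N + 1)
    _, counts = np.unique(allv, return_counts=True)
    correction = 1.0 - float(np.sum(counts**3 - counts)) / (N**3 - N)
    return H / correction


def naive_dunn_z(values: np.ndarray, groups: np.ndarray, a, b) -> float:
    """Dunn's z for one group pair from the tie-corrected rank variance."""
    ranks = _avg_ranks(np.asarray(values, float))
    N = len(values)
    _, counts = np.unique(values, return_counts=True)
    T = float(np.sum(counts**3 - counts))
    ra = ranks[groups == a]
    rb = ranks[groups == b]
    var = (N * (N + 1) / 12.0 - T / (12.0 * (N - 1))) * (1 / len(ra) + 1 / len(rb))
    return float((ra.mean() - rb.mean()) / sqrt(var))


def naive_bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values by the textbook recursion."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        val = min(prev, p[idx] * m / rank_from_top)
        q[idx] = val
        prev = val
    return q


def naive_fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full hypergeometric enumeration: sum the
    probabilities of all tables with the same margins whose probability is
    <= the observed table's."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x: int) -> float:
        # P(X = x) for X ~ Hypergeom(n, r1, c1)
        if x < 0 or x > r1 or c1 - x < 0 or c1 - x > r2:
            return 0.0
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    return float(sum(prob(x) for x in range(0, c1 + 1) if prob(x) <= p_obs * (1 + 1e-9)))


def brute_permanova_f(D: np.ndarray, X: np.ndarray) -> float:
    """Pseudo-F via explicit matrices: G = -1/2 J D^2 J, H = X(X'X)^-1 X'
    with X including an intercept column."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (D**2) @ J
    H = X @ np.linalg.pinv(X.T @ X) @ X.T
    q = np.linalg.matrix_rank(X) - 1
    num = np.trace(H @ G @ H) / q
    den = np.trace((np.eye(n) - H) @ G @ (np.eye(n) - H)) / (n - q - 1)
    return float(num / den)


def brute_permanova_exact_p(D: np.ndarray, covariate: np.ndarray) -> float:
    """Exact permutation p by enumerating all n! relabelings."""
    n = D.shape[0]
    if covariate.dtype.kind in "OUS":
        levels = sorted(set(covariate))
        X0 = np.column_stack(
            [np.ones(n)] + [(covariate == lv).astype(float) for lv in levels[:-1]]
        )
    else:
        X0 = np.column_stack([np.ones(n), covariate.astype(float)])
    f_obs = brute_permanova_f(D, X0)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        Xp = X0[list(perm)]
        if brute_permanova_f(D, Xp) >= f_obs - 1e-12:
            count += 1
        total += 1
    return count / total


def brute_unifrac_generalized(
    branches: list[tuple[float, list[str]]],
    pa: dict[str, float],
    pb: dict[str, float],
    alpha: float,
) -> float:
    """Generalized UniFrac by direct per-branch summation over an explicit
    branch list: (length, descendant leaf names)."""
    num = den = 0.0
    for length, leaves in branches:
        qa = sum(pa.get(l, 0.0) for l in leaves)
        qb = sum(pb.get(l, 0.0) for l in leaves)
        tot = qa + qb
        if tot == 0:
            continue
        w = length * tot**alpha
        num += w * abs(qa - qb) / tot
        den += w
    return num / den if den else 0.0


def brute_unifrac_unweighted(
    branches: list[tuple[float, list[str]]],
    pa: dict[str, float],
    pb: dict[str, float],
) -> float:
    num = den = 0.0
    for length, leaves in branches:
        qa = sum(pa.get(l, 0.0) for l in leaves)
        qb = sum(pb.get(l, 0.0) for l in leaves)
        if qa + qb == 0:
            continue
        den += length
        if (qa > 0) != (qb > 0):
            num += length
    return num / den if den else 0.0
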