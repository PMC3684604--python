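"""Distance-based permutation MANOVA (PERMANOVA) and a multi-distance
omnibus (PermanovaG).

PERMANOVA regresses a squared distance matrix on a covariate design: with
the Gower-centered matrix G = -1/2 J D^2 J (J the centering matrix) and the
hat matrix H of the design (intercept + covariate, one-hot for groups), the
pseudo-F statistic is

    F = [tr(HGH)/q] / [tr((I-H)G(I-H)) / (n - q - 1)]

with q the covariate rank. Significance comes from permuting sample labels;
the p-value counts the observed statistic among the permuted ones
(add-one rule), so p is never 0 and the floor is 1/(n_perm + 1).

The omnibus test runs the same permutations jointly across a family of
distance matrices and uses the minimum per-matrix p as the combined
statistic, with its null distribution read off the joint permutations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import factorial

import numpy as np
import pandas as pd
from skbio import DistanceMatrix


@dataclass
class PermanovaResult:
    pseudo_F: float
    p_value: float
    n_permutations: int
    covariate: str = ""
    distance: str = ""
    seed: int | None = None
    q: int = 1
    n: int = 0


@dataclass
class PermanovaGResult:
    per_matrix: list[PermanovaResult]
    omnibus_p: float
    n_permutations: int = 0
    seed: int | None = None


def _gower_center(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    a = -0.5 * d**2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def _design_basis(covariate: np.ndarray) -> np.ndarray:
    """Orthonormal basis Q (n x q) for the centered covariate design.

    Numeric vectors give the regression form (q = 1); string/object vectors
    are one-hot encoded group indicators (q = k - 1 after centering).
    """
    cov = np.asarray(covariate)
    if cov.dtype.kind in "OUS" or cov.dtype == bool:
        levels, codes = np.unique(cov, return_inverse=True)
        if len(levels) < 2:
            raise ValueError("zero-variance covariate")
        X = np.eye(len(levels))[codes][:, :-1]
    else:
        cov = cov.astype(float)
        if np.ptp(cov) == 0:
            raise ValueError("zero-variance covariate")
        X = cov[:, None]
    Xc = X - X.mean(axis=0, keepdims=True)
    Q, R = np.linalg.qr(Xc)
    keep = np.abs(np.diag(R)) > 1e-10 * max(1.0, np.abs(np.diag(R)).max())
    Q = Q[:, keep]
    if Q.shape[1] == 0:
        raise ValueError("zero-variance covariate")
    return Q


def _pseudo_f(trGH: np.ndarray, trG: float, q: int, n: int) -> np.ndarray:
    denom = (trG - trGH) / (n - q - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return (trGH / q) / denom


def _permuted_trGH(G: np.ndarray, Q: np.ndarray, perms: np.ndarray) -> np.ndarray:
    """tr(G H_pi) for each permutation pi (rows of ``perms``).

    Because G is double-centered the intercept part of H contributes
    nothing, so tr(G H_pi) = tr(Q_pi' G Q_pi) with Q_pi = Q[pi].
    """
    out = np.empty(len(perms))
    chunk = max(1, int(2e7 // max(G.shape[0] * Q.shape[1], 1)))
    for start in range(0, len(perms), chunk):
        block = perms[start : start + chunk]
        Qp = Q[block]  # (m, n, q)
        out[start : start + len(block)] = np.einsum("mnq,nk,mkq->m", Qp, G, Qp)
    return out


def permanova(
    d: DistanceMatrix | np.ndarray,
    covariate,
    n_perm: int = 9999,
    seed: int | None = None,
    *,
    exact: bool = False,
    covariate_name: str = "",
    distance_name: str = "",
) -> PermanovaResult:
    """PERMANOVA of one distance matrix against one covariate.

    Parameters
    ----------
    d:
        Square symmetric distance matrix (skbio ``DistanceMatrix`` or array).
    covariate:
        Per-sample values aligned to ``d``'s sample order: numeric for the
        regression form, strings/bools for group labels. A ``pd.Series``
        indexed by sample id is re-aligned to the matrix ids.
    n_perm:
        Number of random label permutations (>= 99 recommended).
    exact:
        Enumerate all n! permutations instead of sampling; the p-value is
        then the exact permutation p (observed included via the identity
        permutation). Only sensible for very small n.
    """
    if isinstance(d, DistanceMatrix):
        ids = list(d.ids)
        dmat = d.data
    else:
        dmat = np.asarray(d, dtype=float)
        ids = list(range(dmat.shape[0]))
    if isinstance(covariate, pd.Series):
        covariate = covariate.reindex(ids).to_numpy()
    cov = np.asarray(covariate)
    n = dmat.shape[0]
    if cov.shape[0] != n:
        raise ValueError(f"covariate length {cov.shape[0]} != n samples {n}")

    G = _gower_center(dmat)
    Q = _design_basis(cov)
    q = Q.shape[1]
    trG = float(np.trace(G))
    if trG <= 1e-12:
        # all distances (numerically) zero: no community variation to explain
        return PermanovaResult(
            pseudo_F=0.0, p_value=1.0, n_permutations=0,
            covariate=covariate_name, distance=distance_name, seed=seed, q=q, n=n,
        )
    f_obs = float(_pseudo_f(np.array([np.einsum("nq,nk,kq->", Q, G, Q)]), trG, q, n)[0])

    if exact:
        perms = np.array(list(itertools.permutations(range(n))))
        f_perm = _pseudo_f(_permuted_trGH(G, Q, perms), trG, q, n)
        p = float(np.sum(f_perm >= f_obs - 1e-12) / factorial(n))
        n_used = len(perms)
    else:
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(n) for _ in range(n_perm)])
        f_perm = _pseudo_f(_permuted_trGH(G, Q, perms), trG, q, n)
        p = float((1 + np.sum(f_perm >= f_obs - 1e-12)) / (1 + n_perm))
        n_used = n_perm
    return PermanovaResult(
        pseudo_F=f_obs,
        p_value=p,
        n_permutations=n_used,
        covariate=covariate_name,
        distance=distance_name,
        seed=seed,
        q=q,
        n=n,
    )


def permanova_g(
    ds: dict[str, DistanceMatrix] | list[DistanceMatrix],
    covariate,
    n_perm: int = 9999,
    seed: int | None = None,
    *,
    covariate_name: str = "",
) -> PermanovaGResult:
    """Omnibus PERMANOVA over a family of distance matrices.

    The same label permutations are applied jointly to every matrix; the
    combined statistic is the minimum per-matrix p-value, whose null
    distribution is computed from the joint permutations (each permuted
    dataset gets its own min-p from the ranks of its pseudo-F values within
    the permutation distribution).
    """
    if isinstance(ds, dict):
        names, mats = list(ds.keys()), list(ds.values())
    else:
        names = [f"d{i}" for i in range(len(ds))]
        mats = list(ds)
    if not mats:
        raise ValueError("no distance matrices supplied")
    base_ids = list(mats[0].ids) if isinstance(mats[0], DistanceMatrix) else None
    for m in mats[1:]:
        m_ids = list(m.ids) if isinstance(m, DistanceMatrix) else None
        if m_ids != base_ids:
            raise ValueError("distance matrices do not share the same sample set/order")
    if isinstance(covariate, pd.Series) and base_ids is not None:
        covariate = covariate.reindex(base_ids).to_numpy()
    cov = np.asarray(covariate)

    n = mats[0].shape[0]
    Q = _design_basis(cov)
    q = Q.shape[1]
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])

    per_matrix: list[PermanovaResult] = []
    # pseudo-p of each permutation within each matrix, for the min-p null
    pseudo_p = np.empty((len(mats), n_perm))
    for mi, (name, m) in enumerate(zip(names, mats)):
        dmat = m.data if isinstance(m, DistanceMatrix) else np.asarray(m, float)
        G = _gower_center(dmat)
        trG = float(np.trace(G))
        f_obs = float(_pseudo_f(np.array([np.einsum("nq,nk,kq->", Q, G, Q)]), trG, q, n)[0])
        f_perm = _pseudo_f(_permuted_trGH(G, Q, perms), trG, q, n)
        p = float((1 + np.sum(f_perm >= f_obs - 1e-12)) / (1 + n_perm))
        per_matrix.append(
            PermanovaResult(
                pseudo_F=f_obs,
                p_value=p,
                n_permutations=n_perm,
                covariate=covariate_name,
                distance=name,
                seed=seed,
                q=q,
                n=n,
            )
        )
        # pseudo-p of permutation k within the permutation distribution:
        # #{j: F_j >= F_k} / n_perm (k counts itself, keeping the same floor
        # as the observed p)
        sorted_desc = -np.sort(-f_perm)
        ge_counts = np.searchsorted(-sorted_desc, -f_perm, side="right")
        pseudo_p[mi] = ge_counts / n_perm

    obs_min_p = min(r.p_value for r in per_matrix)
    null_min_p = pseudo_p.min(axis=0)
    omnibus_p = float((1 + np.sum(null_min_p <= obs_min_p + 1e-15)) / (1 + n_perm))
    return PermanovaGResult(
        per_matrix=per_matrix,
        omnibus_p=omnibus_p,
        n_permutations=n_perm,
        seed=seed,
    )
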