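"""Pairwise and groupwise association statistics.

Covers the co-occurrence screen (presence calls at a proportion threshold,
Dice similarity, Ward ordering of Dice profiles), the archaeal-status
grouping with Kruskal-Wallis / Dunn tests, Spearman correlation matrices,
Fisher's exact 2x2, the Prevotella/Bacteroides log-ratio covariate, z-score
heatmap summaries, genus richness, and Benjamini-Hochberg FDR tiers.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .tables import CountTable, ProportionTable

#: FDR tiers marked with 1..4 asterisks on heatmaps.
FDR_TIERS: tuple[float, ...] = (0.25, 0.20, 0.15, 0.10)

NO_ARCHAEA = "none"


@dataclass
class AssociationResult:
    """One tested pair or group contrast."""

    feature_a: str
    feature_b: str
    test: str
    statistic: float
    p_raw: float
    q_bh: float = float("nan")
    n: int = 0
    flagged: bool = False  # undefined statistic (constant input etc.)


@dataclass
class ArchaealStatus:
    """Per-sample archaeal category: one of the two dominant archaeal
    genera, or ``none``."""

    labels: pd.Series  # sample id -> label
    warnings: list[str] = field(default_factory=list)

    @property
    def groups(self) -> list[str]:
        return sorted(self.labels.unique())


# ---------------------------------------------------------------------------
# presence / co-occurrence


def _as_df(table: ProportionTable | pd.DataFrame) -> pd.DataFrame:
    return table.df if isinstance(table, ProportionTable) else table


def presence_matrix(
    props: ProportionTable | pd.DataFrame, threshold: float = 0.01
) -> pd.DataFrame:
    """Binary genus x sample matrix; present iff proportion >= threshold
    (inclusive). At threshold 0 everything is marked present; use a strictly
    positive threshold for nonzero detection."""
    return (_as_df(props) >= threshold).astype(np.int8)


def dice_matrix(presence: pd.DataFrame) -> pd.DataFrame:
    """Dice co-occurrence similarity S(i,j) = 2|A∩B| / (|A|+|B|) over the
    sample-presence sets of each genus pair; diagonal 1; a pair of
    never-present genera is assigned 0 so the matrix stays complete for
    clustering."""
    if presence.shape[0] < 2:
        raise ValueError("need at least 2 genera for a Dice matrix")
    M = presence.to_numpy(dtype=float)
    inter = M @ M.T
    sizes = M.sum(axis=1)
    denom = sizes[:, None] + sizes[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        S = np.where(denom > 0, 2.0 * inter / np.where(denom > 0, denom, 1.0), 0.0)
    np.fill_diagonal(S, 1.0)
    return pd.DataFrame(S, index=presence.index, columns=presence.index)


def dice_cluster_order(S: pd.DataFrame) -> tuple[list[str], np.ndarray]:
    """Ward clustering of genera on the Euclidean distances between their
    Dice profiles (each genus's feature vector is its row of S). Returns the
    dendrogram leaf order and the scipy linkage matrix."""
    if S.shape[0] < 2:
        raise ValueError("need at least 2 genera to cluster")
    Z = linkage(pdist(S.to_numpy(), metric="euclidean"), method="ward")
    order = [S.index[i] for i in leaves_list(Z)]
    return order, Z


# ---------------------------------------------------------------------------
# archaeal status


def classify_archaeal_status(
    arch_props: ProportionTable | pd.DataFrame,
    target_genera: tuple[str, str] = ("Methanobrevibacter", "Nitrososphaera"),
) -> ArchaealStatus:
    """Assign each sample to one of the two target archaeal genera (the
    predominant one when both are detected) or ``none``. An exact nonzero
    tie is assigned ``none`` with a recorded warning."""
    df = _as_df(arch_props)
    a, b = target_genera
    pa = df.loc[a] if a in df.index else pd.Series(0.0, index=df.columns)
    pb = df.loc[b] if b in df.index else pd.Series(0.0, index=df.columns)
    labels = {}
    warns: list[str] = []
    for s in df.columns:
        va, vb = float(pa[s]), float(pb[s])
        if va == 0 and vb == 0:
            labels[s] = NO_ARCHAEA
        elif va > vb:
            labels[s] = a
        elif vb > va:
            labels[s] = b
        else:
            labels[s] = NO_ARCHAEA
            warns.append(f"sample {s}: exact tie between {a} and {b}; assigned {NO_ARCHAEA}")
    return ArchaealStatus(labels=pd.Series(labels), warnings=warns)


# ---------------------------------------------------------------------------
# rank tests


def kruskal_wallis(
    values: pd.Series | np.ndarray,
    groups: pd.Series | np.ndarray,
    *,
    feature: str = "",
    factor: str = "group",
) -> AssociationResult:
    """Kruskal-Wallis rank test across >= 2 non-empty groups, tie-corrected,
    chi-square p with k-1 df. When every value is identical the statistic is
    undefined through the tie correction; it is defined here as H = 0,
    p = 1."""
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    levels = np.unique(g)
    if len(levels) < 2:
        raise ValueError("need >= 2 groups")
    samples = [v[g == lev] for lev in levels]
    if any(len(s) == 0 for s in samples):
        raise ValueError("empty group after alignment")
    if np.ptp(v) == 0:
        return AssociationResult(feature, factor, "kruskal-wallis", 0.0, 1.0, n=len(v))
    H, p = stats.kruskal(*samples)
    return AssociationResult(feature, factor, "kruskal-wallis", float(H), float(p), n=len(v))


def dunn_posthoc(
    values: pd.Series | np.ndarray,
    groups: pd.Series | np.ndarray,
    *,
    feature: str = "",
) -> list[AssociationResult]:
    """Dunn's pairwise post-hoc after Kruskal-Wallis: z = (mean-rank
    difference) / SE with the tie-corrected SE, two-sided normal p, BH
    adjustment across the pairs."""
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    levels = list(np.unique(g))
    if len(levels) < 2:
        raise ValueError("need >= 2 groups")
    N = len(v)
    ranks = stats.rankdata(v)
    _, tie_counts = np.unique(v, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    results: list[AssociationResult] = []
    for la, lb in itertools.combinations(levels, 2):
        ra, rb = ranks[g == la], ranks[g == lb]
        na, nb = len(ra), len(rb)
        if na == 0 or nb == 0:
            raise ValueError("empty group after alignment")
        var = (N * (N + 1) / 12.0 - tie_term / (12.0 * (N - 1))) * (1.0 / na + 1.0 / nb)
        if var <= 0:
            z = 0.0
        else:
            z = float((ra.mean() - rb.mean()) / np.sqrt(var))
        p = float(2 * stats.norm.sf(abs(z)))
        results.append(
            AssociationResult(str(la), str(lb), "dunn", z, min(p, 1.0), n=na + nb)
        )
    qvals, _ = bh_fdr([r.p_raw for r in results])
    for r, q in zip(results, qvals):
        r.q_bh = float(q)
    return results


def spearman_matrix(
    x_props: ProportionTable | pd.DataFrame,
    y_table: ProportionTable | pd.DataFrame,
    *,
    test_name: str = "spearman",
) -> list[AssociationResult]:
    """All-pairs Spearman rank correlations between the features (rows) of
    two tables sharing a sample set, with two-sided p and BH q across the
    whole matrix (constant features are flagged and excluded from the FDR
    family)."""
    X = x_props.df if isinstance(x_props, ProportionTable) else x_props
    Y = y_table.df if isinstance(y_table, ProportionTable) else y_table
    shared = [s for s in X.columns if s in set(Y.columns)]
    if not shared:
        raise ValueError("no shared samples")
    X, Y = X[shared], Y[shared]
    results: list[AssociationResult] = []
    for fa in X.index:
        xa = X.loc[fa].to_numpy(dtype=float)
        for fb in Y.index:
            yb = Y.loc[fb].to_numpy(dtype=float)
            if np.ptp(xa) == 0 or np.ptp(yb) == 0:
                results.append(
                    AssociationResult(str(fa), str(fb), test_name, float("nan"), float("nan"),
                                      n=len(shared), flagged=True)
                )
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rho, p = stats.spearmanr(xa, yb)
            results.append(
                AssociationResult(str(fa), str(fb), test_name, float(rho), float(p), n=len(shared))
            )
    attach_bh(results)
    return results


# ---------------------------------------------------------------------------
# FDR


def bh_fdr(p_values, q: float = 0.25) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up q-values and the selection mask at level
    ``q``. q-values are monotone over sorted p."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    reject, qvals, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return qvals, reject


def fdr_tiers(qvals) -> list[int]:
    """Number of asterisks (0-4) per test: tiers at q <= 0.25/0.20/0.15/0.10."""
    return [int(sum(qv <= t for t in FDR_TIERS)) for qv in np.asarray(qvals, float)]


def attach_bh(results: list[AssociationResult], q: float = 0.25) -> np.ndarray:
    """Compute BH q-values over one declared FDR family (one heatmap/panel),
    skipping flagged results; returns the selection mask aligned to the
    unflagged subset."""
    ok = [r for r in results if not r.flagged]
    if not ok:
        return np.array([], dtype=bool)
    qvals, mask = bh_fdr([r.p_raw for r in ok], q=q)
    for r, qv in zip(ok, qvals):
        r.q_bh = float(qv)
    return mask


# ---------------------------------------------------------------------------
# misc statistics


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> AssociationResult:
    """Two-sided Fisher's exact test on [[a, b], [c, d]] by the
    minimum-likelihood rule (sum over tables with hypergeometric probability
    <= the observed table's)."""
    tab = np.array([[a, b], [c, d]])
    if tab.min() < 0:
        raise ValueError("counts must be non-negative")
    if tab.sum() == 0:
        raise ValueError("all-zero 2x2 table")
    odds, p = stats.fisher_exact(tab, alternative="two-sided")
    return AssociationResult("row", "col", "fisher-exact", float(odds), float(p), n=int(tab.sum()))


def pb_ratio(
    bact_props: ProportionTable | pd.DataFrame,
    pseudocount: float = 1e-6,
    *,
    prevotella: str = "Prevotella",
    bacteroides: str = "Bacteroides",
) -> pd.Series:
    """Per-sample log10 Prevotella/Bacteroides ratio with a pseudocount on
    both proportions; the continuous "enterotype axis" covariate."""
    df = _as_df(bact_props)
    for g in (prevotella, bacteroides):
        if g not in df.index:
            raise KeyError(f"genus {g!r} not present in the bacterial table")
    p = df.loc[prevotella].astype(float)
    b = df.loc[bacteroides].astype(float)
    return np.log10((p + pseudocount) / (b + pseudocount))


def group_zscore_summary(
    props: ProportionTable | pd.DataFrame, status: ArchaealStatus | pd.Series
) -> pd.DataFrame:
    """Feature x group matrix of group means of per-feature z-scores (z
    taken across all samples). Zero-variance features give all-zero rows."""
    df = props.df if isinstance(props, ProportionTable) else props
    labels = status.labels if isinstance(status, ArchaealStatus) else status
    shared = [s for s in df.columns if s in labels.index]
    df = df[shared]
    labels = labels.loc[shared]
    if labels.nunique() < 2:
        raise ValueError("need >= 2 groups represented")
    mat = df.to_numpy(dtype=float)
    mu = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, ddof=1, keepdims=True)
    z = np.where(sd > 0, (mat - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    zdf = pd.DataFrame(z, index=df.index, columns=df.columns)
    out = {g: zdf.loc[:, (labels == g).to_numpy()].mean(axis=1) for g in sorted(labels.unique())}
    return pd.DataFrame(out)


def genus_richness(
    table: CountTable | ProportionTable | pd.DataFrame, threshold: float | None = None
) -> pd.Series:
    """Number of detected genera per sample: count > 0, or proportion >=
    threshold when one is given."""
    df = table.df if not isinstance(table, pd.DataFrame) else table
    if threshold is None:
        return (df > 0).sum(axis=0)
    return (df >= threshold).sum(axis=0)
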