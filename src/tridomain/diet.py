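"""Dietary-pattern dimension reduction and the diet screening workflow.

Nutrient inventories carry a couple of hundred strongly inter-correlated
variables. To tame multiple testing, nutrients are grouped by rank
correlation into a small number of clusters (about 10% of the nutrient
count, default 20), and each cluster is summarized by the first principal
component of its z-standardized members — the per-sample "nutrient cluster
measurement" (NCM) used as a surrogate dietary covariate.

Each inventory (usual / recent) is clustered separately. Screening is
two-stage: each NCM is first tested against community structure with
PERMANOVA on the UniFrac family; only screened-in clusters proceed to
genus-level Spearman correlations and archaeal-status Kruskal-Wallis tests,
each stage-2 family BH-adjusted on its own.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA

from .associations import ArchaealStatus, AssociationResult, attach_bh, kruskal_wallis, spearman_matrix
from .permanova import PermanovaResult, permanova
from .tables import NutrientTable, ProportionTable


@dataclass
class NutrientClusterMeasurement:
    """Per-sample cluster scores plus the reduction's bookkeeping."""

    inventory: str
    scores: pd.DataFrame  # sample x cluster
    membership: dict[str, str]  # nutrient -> cluster id
    loadings: dict[str, pd.Series]  # cluster id -> PC1 loadings over members
    explained_variance: dict[str, float]
    excluded_constant: list[str] = field(default_factory=list)

    @property
    def cluster_ids(self) -> list[str]:
        return list(self.scores.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.index)


def _zscore(df: pd.DataFrame) -> pd.DataFrame:
    mu = df.mean(axis=0)
    sd = df.std(axis=0, ddof=1)
    return (df - mu) / sd


def nutrient_cluster_measurements(
    nut: NutrientTable, n_clusters: int = 20
) -> NutrientClusterMeasurement:
    """Cluster nutrients on 1 - Spearman rho (Ward linkage on the
    square-root embedding) into ``n_clusters`` groups, then extract PC1 of
    the z-standardized members of each cluster.

    PC1 sign convention: each score is oriented so that its correlation with
    the mean of the member z-scores is non-negative (scores are otherwise
    sign-ambiguous). A singleton cluster's score is the z-scored nutrient
    itself. Constant nutrient columns are excluded up front with a warning.
    """
    const = nut.constant_nutrients
    if const:
        warnings.warn(f"excluding constant nutrients: {const}")
    df = nut.df.drop(columns=const)
    if df.shape[1] < n_clusters:
        raise ValueError(
            f"need >= {n_clusters} non-constant nutrients, have {df.shape[1]}"
        )
    rho = df.corr(method="spearman").to_numpy()
    # 1 - rho in [0, 2]; sqrt embedding keeps Ward's Euclidean geometry honest
    diss = np.sqrt(np.clip(1.0 - rho, 0.0, None))
    np.fill_diagonal(diss, 0.0)
    Z = linkage(squareform(diss, checks=False), method="ward")
    assignments = fcluster(Z, t=n_clusters, criterion="maxclust")

    membership: dict[str, str] = {}
    scores: dict[str, pd.Series] = {}
    loadings: dict[str, pd.Series] = {}
    explained: dict[str, float] = {}
    for c in sorted(set(assignments)):
        cid = f"cluster_{c:02d}"
        members = [n for n, a in zip(df.columns, assignments) if a == c]
        for m in members:
            membership[m] = cid
        zs = _zscore(df[members])
        if len(members) == 1:
            s = zs.iloc[:, 0]
            loadings[cid] = pd.Series([1.0], index=members)
            explained[cid] = 1.0
        else:
            pca = PCA(n_components=1)
            s = pd.Series(pca.fit_transform(zs.to_numpy())[:, 0], index=df.index)
            loadings[cid] = pd.Series(pca.components_[0], index=members)
            explained[cid] = float(pca.explained_variance_ratio_[0])
        ref = zs.mean(axis=1)
        if np.corrcoef(s.to_numpy(), ref.to_numpy())[0, 1] < 0:
            s = -s
            loadings[cid] = -loadings[cid]
        scores[cid] = s - s.mean()
    score_df = pd.DataFrame(scores, index=df.index)
    return NutrientClusterMeasurement(
        inventory=nut.inventory,
        scores=score_df,
        membership=membership,
        loadings=loadings,
        explained_variance=explained,
        excluded_constant=const,
    )


@dataclass
class ScreenReport:
    """Stage-1 PERMANOVA screen and stage-2 post-hoc results."""

    stage1: list[PermanovaResult]
    screened_clusters: list[str]
    spearman: list[AssociationResult]
    kruskal: list[AssociationResult]
    alpha: float
    q: float


def screen_and_posthoc(
    ncm: NutrientClusterMeasurement,
    dists: dict[str, "object"],
    taxa_props: ProportionTable | pd.DataFrame,
    status: ArchaealStatus | None,
    n_perm: int = 999,
    seed: int | None = None,
    q: float = 0.25,
    alpha: float = 0.05,
) -> ScreenReport:
    """Two-stage diet screen.

    Stage 1: PERMANOVA of each cluster score against each distance matrix;
    a cluster is screened in if any of its tests has raw p < ``alpha``.
    Stage 2 (screened clusters only): Spearman of the cluster score against
    each genus proportion (one BH family) and Kruskal-Wallis of the score
    across archaeal status (another BH family), both at FDR ``q``.
    """
    stage1: list[PermanovaResult] = []
    screened: list[str] = []
    for ci, cid in enumerate(ncm.cluster_ids):
        hit = False
        for di, (dname, dm) in enumerate(dists.items()):
            ids = list(dm.ids)
            cov = ncm.scores[cid].reindex(ids)
            res = permanova(
                dm,
                cov,
                n_perm=n_perm,
                seed=None if seed is None else seed + 1000 * ci + di,
                covariate_name=cid,
                distance_name=dname,
            )
            stage1.append(res)
            hit = hit or res.p_value < alpha
        if hit:
            screened.append(cid)

    taxa_df = taxa_props.df if isinstance(taxa_props, ProportionTable) else taxa_props
    spearman_results: list[AssociationResult] = []
    kw_results: list[AssociationResult] = []
    if screened:
        score_rows = ncm.scores[screened].T  # cluster x sample
        spearman_results = spearman_matrix(score_rows, taxa_df, test_name="spearman-diet")
        if status is not None:
            labels = status.labels
            shared = [s for s in ncm.sample_ids if s in labels.index]
            for cid in screened:
                kw_results.append(
                    kruskal_wallis(
                        ncm.scores[cid].loc[shared].to_numpy(),
                        labels.loc[shared].to_numpy(),
                        feature=cid,
                        factor="archaeal_status",
                    )
                )
            attach_bh(kw_results, q=q)
    return ScreenReport(
        stage1=stage1,
        screened_clusters=screened,
        spearman=spearman_results,
        kruskal=kw_results,
        alpha=alpha,
        q=q,
    )
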