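"""Synthetic tri-domain cohort generator and robustness simulations.

Emulates the statistical structure the analysis assumes, so that every
pipeline stage is testable without any sequence data: three domain-specific
sparse genus count tables over a shared sample set (default n = 96) with
Dirichlet-multinomial noise; near-mutually-exclusive archaeal occupancy by
the two dominant archaeal genera; a reciprocal Prevotella/Bacteroides axis
driven by a per-sample latent variable; and two nutrient inventories with
block-exchangeable correlation plus optional planted taxon-nutrient and
taxon-archaeal-status effects. Ground truth for every planted feature is
returned alongside the tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .permanova import permanova
from .tables import CountTable, Domain, NutrientTable, TaxonomyTable, UNCLASSIFIED

MBB = "Methanobrevibacter"
NIT = "Nitrososphaera"


@dataclass
class PlantedTaxonNutrientEffect:
    """Gaussian-copula link between a genus's latent abundance and one
    nutrient block's latent score: rho is the latent-scale correlation."""

    domain: Domain
    genus: str
    inventory: str  # "usual" | "recent"
    block: int
    rho: float


@dataclass
class PlantedTaxonStatusEffect:
    """Log-scale mean shift of a genus in samples with the given archaeal
    status."""

    domain: Domain
    genus: str
    status: str
    shift: float


@dataclass
class CohortConfig:
    """Generator settings; defaults mirror the study's cohort margins."""

    n_samples: int = 96
    n_bacteria: int = 40
    n_fungi: int = 30
    n_archaea: int = 5
    # sequencing depth: log-normal, median ~1000 reads/sample per domain
    depth_log_mean: float = float(np.log(1000.0))
    depth_log_sd: float = 0.5
    dirichlet_concentration: float = 200.0
    base_log_sd: float = 1.5  # spread of baseline genus log-abundances
    sample_log_sd: float = 1.0  # per-sample latent variation per genus
    # archaeal occupancy margins (of n_samples): 24 MBB-only, 10 NIT-only,
    # 6 both -> 40 positive for the two dominant genera; rarer archaeal
    # genera add a few more positives
    p_mbb_only: float = 24 / 96
    p_nit_only: float = 10 / 96
    p_both: float = 6 / 96  # the exclusivity parameter epsilon
    both_share: float = 0.8  # predominant genus share in "both" samples
    p_rare_archaeon: float = 0.03
    # Prevotella/Bacteroides reciprocity: latent u shifts the two log-means
    # in opposite directions by +-pb_strength * u
    pb_strength: float = 2.0
    # nutrients: blocks of exchangeable correlation, zero between blocks
    n_nutrients: int = 200
    n_blocks: int = 20
    within_block_rho: float = 0.7
    between_block_rho: float = 0.0
    #: mean community share of a taxon carrying a planted nutrient effect; a
    #: correlation target is only meaningful for a detectable community
    #: member, so planted taxa are pinned at a stable moderate abundance
    planted_mean_share: float = 0.1
    planted_effects: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_mbb_only, self.p_nit_only, self.p_both, self.p_rare_archaeon):
            if not 0.0 <= p <= 1.0:
                raise ValueError("occupancy probabilities must lie in [0, 1]")
        if self.p_mbb_only + self.p_nit_only + self.p_both > 1.0:
            raise ValueError("archaeal occupancy probabilities exceed 1")
        if self.n_nutrients < self.n_blocks:
            raise ValueError("block count exceeds nutrient count")


@dataclass
class GroundTruth:
    nutrient_blocks: dict[str, dict[str, int]]  # inventory -> nutrient -> block
    block_scores: dict[str, pd.DataFrame]  # inventory -> sample x block latents
    planted_effects: list
    archaeal_state: pd.Series  # sample -> {MBB, NIT, both, none}
    pb_latent: pd.Series


#: Baseline log-abundance offsets for the dominant named genera, mirroring
#: their standing in gut surveys (Saccharomyces/Candida dominate stool
#: mycobiomes; Bacteroides and relatives dominate the bacterial fraction).
BASE_OFFSETS = {
    "Saccharomyces": 2.5,
    "Candida": 2.0,
    "Cladosporium": 0.8,
    "Aspergillus": 0.5,
    "Bacteroides": 2.0,
    "Prevotella": 1.5,
    "Ruminococcaceae": 1.5,
    "Lachnospiraceae": 1.5,
    "Faecalibacterium": 1.2,
    "Parabacteroides": 0.8,
    "Ruminococcus": 0.8,
}


def _bacterial_names(n: int) -> list[str]:
    named = [
        "Prevotella", "Bacteroides", "Parabacteroides", "Ruminococcus",
        "Faecalibacterium", "Lachnospiraceae", "Ruminococcaceae", "Alistipes",
        "Blautia", "Oscillibacter",
    ]
    return (named + [f"BactGenus{i:02d}" for i in range(n)])[:n]


def _fungal_names(n: int) -> list[str]:
    named = ["Saccharomyces", "Candida", "Cladosporium", "Aspergillus", "Penicillium", "Debaryomyces"]
    return (named + [f"FungGenus{i:02d}" for i in range(n)])[:n]


def _archaeal_names(n: int) -> list[str]:
    named = [MBB, NIT, "Methanosphaera", "Thermogymnomonas", "Methanobacterium"]
    return (named + [f"ArchGenus{i:02d}" for i in range(n)])[:n]


def _synthetic_taxonomy(
    genera: list[str], phyla: list[str], rng: np.random.Generator
) -> TaxonomyTable:
    """Random but hierarchy-consistent 5-rank lineages over given phyla."""
    rows = {}
    phylum_of = {g: phyla[i % len(phyla)] for i, g in enumerate(genera)}
    for g in genera:
        ph = phylum_of[g]
        cl = f"{ph}_class{rng.integers(1, 3)}"
        od = f"{cl}_order{rng.integers(1, 3)}"
        fa = f"{od}_family{rng.integers(1, 3)}"
        rows[g] = [ph, cl, od, fa, g]
    df = pd.DataFrame.from_dict(rows, orient="index")
    return TaxonomyTable(df=df)


def _curated_fungal_taxonomy(genera: list[str], rng: np.random.Generator) -> TaxonomyTable:
    asc = {"Saccharomyces", "Candida", "Aspergillus", "Penicillium", "Debaryomyces"}
    rows = {}
    for i, g in enumerate(genera):
        ph = "Ascomycota" if (g in asc or (g.startswith("FungGenus") and i % 3 != 0)) else "Basidiomycota"
        if g == "Cladosporium":
            ph = "Ascomycota"
        cl = f"{ph}_class{rng.integers(1, 3)}"
        od = f"{cl}_order{rng.integers(1, 3)}"
        fa = f"{od}_family{rng.integers(1, 3)}"
        rows[g] = [ph, cl, od, fa, g]
    df = pd.DataFrame.from_dict(rows, orient="index")
    return TaxonomyTable(df=df)


def _nutrient_panel(
    cfg: CohortConfig, inventory: str, rng: np.random.Generator, samples: list[str]
) -> tuple[NutrientTable, dict[str, int], pd.DataFrame]:
    """Block-exchangeable correlated nutrient panel.

    Nutrient j in block b is sqrt(rho) * z_b + sqrt(1 - rho) * eps_j (plus an
    optional shared factor for between-block correlation), scaled and
    shifted to look like intake totals.
    """
    n, p, B = cfg.n_samples, cfg.n_nutrients, cfg.n_blocks
    sizes = np.full(B, p // B)
    sizes[: p % B] += 1
    z = rng.standard_normal((n, B))
    shared = rng.standard_normal((n, 1))
    rho_w, rho_b = cfg.within_block_rho, cfg.between_block_rho
    cols = {}
    membership = {}
    j = 0
    for b in range(B):
        for _ in range(sizes[b]):
            name = f"{inventory}_nutrient_{j:03d}"
            eps = rng.standard_normal(n)
            x = (
                np.sqrt(max(rho_w - rho_b, 0.0)) * z[:, b]
                + np.sqrt(rho_b) * shared[:, 0]
                + np.sqrt(max(1.0 - rho_w, 0.0)) * eps
            )
            scale = float(np.exp(rng.normal(2.0, 1.0)))  # unit-bearing spread
            cols[name] = scale * x + 5.0 * scale
            membership[name] = b
            j += 1
    df = pd.DataFrame(cols, index=samples)
    block_df = pd.DataFrame(z, index=samples, columns=[f"block_{b:02d}" for b in range(B)])
    return NutrientTable(inventory=inventory, df=df), membership, block_df


def generate_cohort(cfg: CohortConfig) -> tuple[dict[Domain, CountTable], dict[Domain, TaxonomyTable], dict[str, NutrientTable], GroundTruth]:
    """Draw one synthetic cohort. All randomness flows from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    samples = [f"S{i:03d}" for i in range(cfg.n_samples)]
    n = cfg.n_samples

    bact = _bacterial_names(cfg.n_bacteria)
    fung = _fungal_names(cfg.n_fungi)
    arch = _archaeal_names(cfg.n_archaea)
    taxonomies = {
        Domain.BACTERIA: _synthetic_taxonomy(
            bact, ["Bacteroidetes", "Firmicutes", "Actinobacteria", "Proteobacteria"], rng
        ),
        Domain.FUNGI: _curated_fungal_taxonomy(fung, rng),
        Domain.ARCHAEA: _synthetic_taxonomy(arch, ["Euryarchaeota", "Thaumarchaeota"], rng),
    }

    # archaeal occupancy state
    u_state = rng.random(n)
    state = np.where(
        u_state < cfg.p_mbb_only,
        "MBB",
        np.where(
            u_state < cfg.p_mbb_only + cfg.p_nit_only,
            "NIT",
            np.where(u_state < cfg.p_mbb_only + cfg.p_nit_only + cfg.p_both, "both", "none"),
        ),
    )
    archaeal_state = pd.Series(state, index=samples)

    # Prevotella/Bacteroides latent axis
    pb_u = rng.standard_normal(n)
    pb_latent = pd.Series(pb_u, index=samples)

    # nutrient panels (each inventory gets its own latent block scores)
    nutrients: dict[str, NutrientTable] = {}
    blocks: dict[str, dict[str, int]] = {}
    block_scores: dict[str, pd.DataFrame] = {}
    for inventory in ("usual", "recent"):
        nut, membership, bscores = _nutrient_panel(cfg, inventory, rng, samples)
        nutrients[inventory] = nut
        blocks[inventory] = membership
        block_scores[inventory] = bscores

    effects_nutrient = [e for e in cfg.planted_effects if isinstance(e, PlantedTaxonNutrientEffect)]
    effects_status = [e for e in cfg.planted_effects if isinstance(e, PlantedTaxonStatusEffect)]

    counts: dict[Domain, CountTable] = {}
    for domain, genera in ((Domain.BACTERIA, bact), (Domain.FUNGI, fung), (Domain.ARCHAEA, arch)):
        g = len(genera)
        base = rng.normal(0.0, cfg.base_log_sd, size=g)
        base += np.array([BASE_OFFSETS.get(name, 0.0) for name in genera])
        # per-sample latent log-abundance deviations
        latent = rng.normal(0.0, cfg.sample_log_sd, size=(g, n))
        logmean = base[:, None] + latent

        if domain == Domain.BACTERIA:
            ip, ib = genera.index("Prevotella"), genera.index("Bacteroides")
            logmean[ip] += cfg.pb_strength * pb_u
            logmean[ib] -= cfg.pb_strength * pb_u

        for e in effects_nutrient:
            if Domain(e.domain) != domain:
                continue
            gi = genera.index(e.genus)
            zb = block_scores[e.inventory].iloc[:, e.block].to_numpy()
            eps = rng.standard_normal(n)
            sign = 1.0 if e.rho >= 0 else -1.0
            # the planted rho is a rank (Spearman) correlation target; on a
            # Gaussian copula that needs Pearson 2*sin(pi*rho/6)
            rho = 2.0 * np.sin(np.pi * abs(e.rho) / 6.0)
            t = rho * zb + np.sqrt(max(1.0 - rho**2, 0.0)) * eps
            # Tie the genus's logit share to t against the realized
            # background, so the Dirichlet-mean proportion is a monotone
            # function of t and the planted rank correlation is not eroded
            # by compositional noise from the other genera.
            others = np.delete(np.arange(g), gi)
            log_bg = np.log(np.exp(logmean[others]).sum(axis=0))
            s = cfg.planted_mean_share
            logmean[gi] = log_bg + np.log(s / (1.0 - s)) + cfg.sample_log_sd * sign * t

        for e in effects_status:
            if Domain(e.domain) != domain:
                continue
            gi = genera.index(e.genus)
            logmean[gi] += np.where(archaeal_state.to_numpy() == e.status, e.shift, 0.0)

        mean_props = np.exp(logmean)
        mean_props /= mean_props.sum(axis=0, keepdims=True)

        depths = np.round(np.exp(rng.normal(cfg.depth_log_mean, cfg.depth_log_sd, size=n))).astype(int)
        depths = np.maximum(depths, 1)

        mat = np.zeros((g, n), dtype=np.int64)
        if domain == Domain.ARCHAEA:
            i_mbb, i_nit = genera.index(MBB), genera.index(NIT)
            rare_idx = [i for i in range(g) if i not in (i_mbb, i_nit)]
            for j in range(n):
                occ = np.zeros(g, dtype=bool)
                st = state[j]
                if st == "MBB":
                    occ[i_mbb] = True
                elif st == "NIT":
                    occ[i_nit] = True
                elif st == "both":
                    occ[i_mbb] = occ[i_nit] = True
                for i in rare_idx:
                    if rng.random() < cfg.p_rare_archaeon:
                        occ[i] = True
                if not occ.any():
                    continue  # archaea-negative sample: zero column
                w = np.zeros(g)
                if st == "both":
                    w[i_mbb], w[i_nit] = cfg.both_share, 1.0 - cfg.both_share
                else:
                    w[occ & ~np.isin(np.arange(g), rare_idx)] = 1.0
                for i in rare_idx:
                    if occ[i]:
                        w[i] = 0.05
                w /= w.sum()
                alpha = cfg.dirichlet_concentration * np.where(w > 0, w, 0)
                pos = alpha > 0
                pvec = np.zeros(g)
                if pos.sum() == 1:
                    pvec[pos] = 1.0
                else:
                    pvec[pos] = rng.dirichlet(alpha[pos])
                mat[:, j] = rng.multinomial(depths[j], pvec)
        else:
            for j in range(n):
                pvec = rng.dirichlet(cfg.dirichlet_concentration * mean_props[:, j])
                mat[:, j] = rng.multinomial(depths[j], pvec)

        counts[domain] = CountTable(
            domain=domain, df=pd.DataFrame(mat, index=genera, columns=samples)
        )

    truth = GroundTruth(
        nutrient_blocks=blocks,
        block_scores=block_scores,
        planted_effects=list(cfg.planted_effects),
        archaeal_state=archaeal_state,
        pb_latent=pb_latent,
    )
    return counts, taxonomies, nutrients, truth


def permanova_type1_calibration(
    n_samples: int = 24,
    n_reps: int = 1000,
    n_perm: int = 99,
    n_dims: int = 5,
    alpha: float = 0.05,
    seed: int = 0,
    covariate: str = "continuous",
) -> float:
    """Empirical PERMANOVA type-I error: a covariate independent of a random
    Euclidean distance matrix, rejection counted at ``alpha``."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        X = rng.standard_normal((n_samples, n_dims))
        diff = X[:, None, :] - X[None, :, :]
        D = np.sqrt((diff**2).sum(axis=2))
        if covariate == "continuous":
            cov = rng.standard_normal(n_samples)
        else:
            cov = np.array(["a", "b"])[rng.integers(0, 2, n_samples)]
            if len(set(cov)) < 2:
                cov[0] = "a" if cov[0] == "b" else "b"
        res = permanova(D, cov, n_perm=n_perm, seed=int(rng.integers(2**31)))
        if res.p_value <= alpha:
            rejections += 1
    return rejections / n_reps


def _null_screen_config(seed: int) -> CohortConfig:
    """Reduced-size cohort used for the repeated null/power screens: the
    calibration properties do not depend on the table sizes, so the screens
    run on fewer taxa and nutrients to keep repeated simulation fast."""
    return CohortConfig(
        n_samples=96, n_bacteria=15, n_fungi=15, n_nutrients=60, n_blocks=6,
        seed=seed,
    )


def null_screen_calibration(
    n_seeds: int = 200, n_perm: int = 99, q: float = 0.25, seed: int = 0
) -> dict[str, float]:
    """Per-family false-selection rates of the two-stage diet screen on
    zero-effect cohorts: for each stage-2 BH family (the Spearman panel and
    the Kruskal-Wallis panel) the fraction of cohorts in which that family
    selects anything at level ``q``. Under the global null every selection
    is false and BH bounds each family's rate by ``q``."""
    from .associations import classify_archaeal_status
    from .diet import nutrient_cluster_measurements, screen_and_posthoc
    from .filtering import filter_genera, to_proportions
    from .taxtree import taxonomy_to_tree, unweighted_unifrac, weighted_unifrac

    rng = np.random.default_rng(seed)
    spearman_hits = 0
    kruskal_hits = 0
    for _ in range(n_seeds):
        cfg = _null_screen_config(int(rng.integers(2**31)))
        counts, taxonomies, nutrients, _ = generate_cohort(cfg)
        ftab, _ = filter_genera(counts[Domain.FUNGI])
        if ftab.df.shape[0] < 2:
            continue
        fprops = to_proportions(ftab)
        tree = taxonomy_to_tree(taxonomies[Domain.FUNGI])
        dists = {
            "weighted": weighted_unifrac(tree, fprops),
            "unweighted": unweighted_unifrac(tree, fprops),
        }
        ncm = nutrient_cluster_measurements(nutrients["recent"], n_clusters=cfg.n_blocks)
        status = classify_archaeal_status(to_proportions(counts[Domain.ARCHAEA]))
        rep = screen_and_posthoc(
            ncm, dists, fprops, status, n_perm=n_perm,
            seed=int(rng.integers(2**31)), q=q,
        )
        if any(r.q_bh <= q for r in rep.spearman if not r.flagged):
            spearman_hits += 1
        if any(r.q_bh <= q for r in rep.kruskal):
            kruskal_hits += 1
    return {
        "spearman_family_rate": spearman_hits / n_seeds,
        "kruskal_family_rate": kruskal_hits / n_seeds,
        "n_seeds": n_seeds,
    }


def planted_effect_detection(
    n_seeds: int = 50,
    rho: float = 0.5,
    q: float = 0.25,
    seed: int = 0,
    genus: str = "Candida",
    inventory: str = "recent",
) -> float:
    """Power of the dietary screen's correlation stage on the planted
    taxon-nutrient effect: fraction of cohorts in which the planted cluster's
    Spearman panel (cluster score vs every filtered fungal genus) selects the
    planted genus with the correct sign at BH level ``q``."""
    from .associations import spearman_matrix
    from .diet import nutrient_cluster_measurements
    from .filtering import filter_genera, to_proportions

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_seeds):
        cfg = CohortConfig(
            seed=int(rng.integers(2**31)),
            planted_effects=[PlantedTaxonNutrientEffect(Domain.FUNGI, genus, inventory, 0, rho)],
        )
        counts, _, nutrients, truth = generate_cohort(cfg)
        ftab, _ = filter_genera(counts[Domain.FUNGI])
        fprops = to_proportions(ftab)
        ncm = nutrient_cluster_measurements(nutrients[inventory], n_clusters=cfg.n_blocks)
        planted_clusters = {
            ncm.membership[n]
            for n, b in truth.nutrient_blocks[inventory].items()
            if b == 0
        }
        panel = ncm.scores[sorted(planted_clusters)].T
        res = spearman_matrix(panel, fprops.df)
        want_sign = 1.0 if rho >= 0 else -1.0
        if any(
            r.feature_b == genus and r.q_bh <= q and r.statistic * want_sign > 0
            for r in res
            if not r.flagged
        ):
            hits += 1
    return hits / n_seeds


def nutrient_block_recovery(n_seeds: int = 10, seed: int = 0) -> float:
    """Mean adjusted Rand index between the generator's nutrient blocks and
    the clustering recovered by the dietary dimension reduction."""
    from sklearn.metrics import adjusted_rand_score

    from .diet import nutrient_cluster_measurements

    rng = np.random.default_rng(seed)
    aris = []
    for _ in range(n_seeds):
        cfg = CohortConfig(seed=int(rng.integers(2**31)))
        _, _, nutrients, truth = generate_cohort(cfg)
        nut = nutrients["usual"]
        ncm = nutrient_cluster_measurements(nut, n_clusters=cfg.n_blocks)
        true_labels = [truth.nutrient_blocks["usual"][n] for n in nut.nutrient_ids]
        pred_labels = [ncm.membership[n] for n in nut.nutrient_ids]
        aris.append(adjusted_rand_score(true_labels, pred_labels))
    return float(np.mean(aris))


def unequal_variance_simulation(
    n_per_group: int = 20,
    dispersion_ratios: tuple[float, ...] = (1.0, 2.0, 4.0),
    n_reps: int = 1000,
    n_perm: int = 99,
    n_dims: int = 5,
    alpha: float = 0.05,
    base_dispersion: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Two groups with equal centroids but unequal multivariate dispersion:
    empirical PERMANOVA rejection rate at ``alpha`` per dispersion ratio.

    A diagnostic of how much heteroscedasticity alone inflates the test; at
    ratio 1 the rate should sit at the nominal level.
    """
    rng = np.random.default_rng(seed)
    labels = np.array(["a"] * n_per_group + ["b"] * n_per_group)
    rows = []
    for r in dispersion_ratios:
        rejections = 0
        for _ in range(n_reps):
            xa = base_dispersion * rng.standard_normal((n_per_group, n_dims))
            xb = base_dispersion * r * rng.standard_normal((n_per_group, n_dims))
            X = np.vstack([xa, xb])
            diff = X[:, None, :] - X[None, :, :]
            D = np.sqrt((diff**2).sum(axis=2))
            res = permanova(D, labels, n_perm=n_perm, seed=int(rng.integers(2**31)))
            if res.p_value <= alpha:
                rejections += 1
        rows.append({"dispersion_ratio": r, "rejection_rate": rejections / n_reps, "n_reps": n_reps})
    return pd.DataFrame(rows)
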