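"""End-to-end analysis driver.

Runs the full graph — depth filter -> proportions -> genus filter ->
taxonomy-tree UniFrac family -> PERMANOVA/PermanovaG screens -> archaeal
status, co-occurrence, z-score summaries -> diet clustering and the
two-stage diet screen — on either a synthetic cohort or user-supplied
tables, writing every matrix and association table as TSV plus a JSON run
manifest sufficient to re-run bit-identically.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .associations import (
    attach_bh,
    classify_archaeal_status,
    dice_cluster_order,
    dice_matrix,
    genus_richness,
    group_zscore_summary,
    kruskal_wallis,
    pb_ratio,
    presence_matrix,
    spearman_matrix,
)
from .cohort import CohortConfig, generate_cohort
from .diet import nutrient_cluster_measurements, screen_and_posthoc
from .filtering import filter_genera, filter_samples_by_depth, to_proportions
from .permanova import permanova, permanova_g
from .tables import CountTable, Domain, NutrientTable, TaxonomyTable
from .taxtree import taxonomy_to_tree, unifrac_family, write_distance_matrix


@dataclass
class PipelineConfig:
    out_dir: str = "tridomain_out"
    seed: int = 7
    n_perm: int = 999
    min_reads_fungi: int = 200
    min_prevalence: int = 9
    min_total: int = 10
    presence_threshold: float = 0.01
    n_nutrient_clusters: int = 20
    fdr_q: float = 0.25
    screen_alpha: float = 0.05
    unifrac_alphas: tuple[float, ...] = (0.0, 0.5, 1.0)
    cohort: CohortConfig | None = None  # None -> caller supplies tables


@dataclass
class RunManifest:
    version: str
    config: dict
    stages: list = field(default_factory=list)

    def record(self, stage: str, **info) -> None:
        self.stages.append({"stage": stage, "time": time.time(), **info})


def _align_samples(tables: dict[Domain, CountTable]) -> tuple[dict[Domain, CountTable], list[str]]:
    """Intersect sample sets across domains; report what was dropped."""
    shared = None
    for t in tables.values():
        s = set(t.sample_ids)
        shared = s if shared is None else shared & s
    dropped = sorted(set().union(*(t.sample_ids for t in tables.values())) - shared)
    out = {}
    for dom, t in tables.items():
        keep = [s for s in t.sample_ids if s in shared]
        out[dom] = CountTable(domain=dom, df=t.df[keep])
    return out, dropped


def run_pipeline(
    config: PipelineConfig,
    counts: dict[Domain, CountTable] | None = None,
    taxonomies: dict[Domain, TaxonomyTable] | None = None,
    nutrients: dict[str, NutrientTable] | None = None,
) -> dict:
    """Execute the full analysis; returns a results dict and writes the
    output tree under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(version=__version__, config={
        **{k: v for k, v in asdict(config).items() if k != "cohort"},
        "cohort": None if config.cohort is None else asdict(config.cohort),
    })

    if counts is None:
        if config.cohort is None:
            raise ValueError("no input tables and no cohort config")
        counts, taxonomies, nutrients, truth = generate_cohort(config.cohort)
        manifest.record("simulate", seed=config.cohort.seed)
    if taxonomies is None or nutrients is None:
        raise ValueError("taxonomies and nutrients are required with explicit counts")

    counts, dropped = _align_samples(counts)
    manifest.record("align_samples", dropped=dropped)

    results: dict = {"manifest": manifest}
    props = {}
    filtered = {}
    for dom, table in counts.items():
        min_reads = config.min_reads_fungi if dom == Domain.FUNGI else 0
        table, rep_depth = filter_samples_by_depth(table, min_reads=min_reads)
        p = to_proportions(table)
        gtab, rep_gen = filter_genera(
            table, min_prevalence=config.min_prevalence, min_total=config.min_total
        )
        report = rep_depth.merged_with(rep_gen)
        report.order = ["depth_filter", "proportions", "genus_filter"]
        props[dom] = p
        filtered[dom] = gtab
        manifest.record(
            f"filter_{dom.value}",
            dropped_samples=[s for s, _ in report.dropped_samples],
            dropped_genera=[g for g, _ in report.dropped_genera],
            thresholds=report.thresholds,
            order=report.order,
        )
        results[f"filter_report_{dom.value}"] = report

    # analysis proportions: proportions restricted to the filtered genus set
    aprops = {
        dom: to_proportions(filtered[dom]) if filtered[dom].df.shape[0] else props[dom]
        for dom in counts
    }

    # distances on the taxonomy tree, per domain
    dists = {}
    for dom in (Domain.BACTERIA, Domain.FUNGI):
        tax = taxonomies[dom]
        keep = [g for g in aprops[dom].genus_ids if g in tax.genus_ids]
        sub = type(aprops[dom])(domain=dom, df=aprops[dom].df.loc[keep],
                                empty_samples=aprops[dom].empty_samples)
        tree = taxonomy_to_tree(tax)
        fam = unifrac_family(tree, sub, alphas=config.unifrac_alphas)
        dists[dom] = fam
        for name, dm in fam.items():
            write_distance_matrix(dm, out / f"dist_{dom.value}_{name}.tsv")
    manifest.record("unifrac", alphas=list(config.unifrac_alphas))

    # archaeal status + screens
    status = classify_archaeal_status(props[Domain.ARCHAEA])
    status.labels.to_csv(out / "archaeal_status.tsv", sep="\t", header=["status"])
    results["archaeal_status"] = status

    seed = config.seed
    pg = {}
    for dom in (Domain.BACTERIA, Domain.FUNGI):
        common = [s for s in dists[dom]["unweighted"].ids if s in status.labels.index]
        fam = {k: dm.filter(common) for k, dm in dists[dom].items()}
        pg[dom.value] = permanova_g(
            fam, status.labels.loc[common], n_perm=config.n_perm, seed=seed,
            covariate_name="archaeal_status",
        )
    results["permanovag_status"] = pg
    manifest.record("permanova_status", omnibus_p={k: v.omnibus_p for k, v in pg.items()})

    # P/B ratio covariate against fungal community
    try:
        ratio = pb_ratio(aprops[Domain.BACTERIA])
        common = [s for s in dists[Domain.FUNGI]["unweighted"].ids if s in ratio.index]
        fam = {k: dm.filter(common) for k, dm in dists[Domain.FUNGI].items()}
        results["permanovag_pb_fungi"] = permanova_g(
            fam, ratio.loc[common], n_perm=config.n_perm, seed=seed + 1,
            covariate_name="pb_ratio",
        )
        posthoc = {
            name: permanova(fam[name], ratio.loc[common], n_perm=config.n_perm,
                            seed=seed + 2, covariate_name="pb_ratio", distance_name=name)
            for name in ("gunifrac_a1", "unweighted") if name in fam
        }
        results["pb_posthoc"] = posthoc
    except KeyError:
        results["permanovag_pb_fungi"] = None

    # co-occurrence across all three domains
    pres_frames = [
        presence_matrix(aprops[dom], threshold=config.presence_threshold)
        for dom in (Domain.BACTERIA, Domain.ARCHAEA, Domain.FUNGI)
        if aprops[dom].df.shape[0]
    ]
    shared_samples = set.intersection(*(set(f.columns) for f in pres_frames))
    pres = pd.concat([f[sorted(shared_samples)] for f in pres_frames], axis=0)
    dice = dice_matrix(pres)
    order, Z = dice_cluster_order(dice)
    dice.loc[order, order].to_csv(out / "dice_matrix.tsv", sep="\t")
    results["dice"] = dice
    results["dice_order"] = order
    manifest.record("cooccurrence", n_genera=dice.shape[0])

    # genus-level cross-domain association heatmaps
    fb = spearman_matrix(aprops[Domain.FUNGI], aprops[Domain.BACTERIA], test_name="spearman-fb")
    results["spearman_fungi_bacteria"] = fb
    kw = []
    for dom in (Domain.BACTERIA, Domain.FUNGI):
        labels = status.labels
        shared = [s for s in aprops[dom].sample_ids if s in labels.index]
        for g in aprops[dom].genus_ids:
            kw.append(
                kruskal_wallis(
                    aprops[dom].df.loc[g, shared].to_numpy(),
                    labels.loc[shared].to_numpy(),
                    feature=g, factor="archaeal_status",
                )
            )
    attach_bh(kw, q=config.fdr_q)
    results["kw_status"] = kw
    results["zscore_status"] = {
        dom.value: group_zscore_summary(aprops[dom], status)
        for dom in (Domain.BACTERIA, Domain.FUNGI)
    }
    results["richness"] = {
        dom.value: genus_richness(counts[dom]) for dom in counts
    }
    manifest.record("associations", n_spearman=len(fb), n_kw=len(kw))

    # diet: cluster each inventory separately, screen against fungal+bacterial
    # distance families, post-hoc against genus proportions and archaeal status
    taxa_df = pd.concat([aprops[Domain.BACTERIA].df, aprops[Domain.FUNGI].df], axis=0)
    diet_reports = {}
    ncms = {}
    for inventory, nut in nutrients.items():
        ncm = nutrient_cluster_measurements(nut, n_clusters=config.n_nutrient_clusters)
        ncms[inventory] = ncm
        screen_d = {
            f"{dom.value}_{name}": dm
            for dom in (Domain.BACTERIA, Domain.FUNGI)
            for name, dm in dists[dom].items()
            if name in ("gunifrac_a1", "unweighted")
        }
        diet_reports[inventory] = screen_and_posthoc(
            ncm, screen_d, taxa_df, status,
            n_perm=config.n_perm, seed=seed + 10, q=config.fdr_q,
            alpha=config.screen_alpha,
        )
        ncm.scores.to_csv(out / f"ncm_{inventory}.tsv", sep="\t")
        pd.Series(ncm.membership).to_csv(out / f"ncm_{inventory}_membership.tsv", sep="\t",
                                         header=["cluster"])
    results["ncm"] = ncms
    results["diet_screens"] = diet_reports
    manifest.record("diet", screened={k: v.screened_clusters for k, v in diet_reports.items()})

    # association tables in long format
    def _assoc_frame(rs):
        return pd.DataFrame(
            [
                {
                    "feature_a": r.feature_a, "feature_b": r.feature_b, "test": r.test,
                    "statistic": r.statistic, "p_raw": r.p_raw, "q_bh": r.q_bh, "n": r.n,
                }
                for r in rs
            ]
        )

    _assoc_frame(fb).to_csv(out / "spearman_fungi_bacteria.tsv", sep="\t", index=False)
    _assoc_frame(kw).to_csv(out / "kw_archaeal_status.tsv", sep="\t", index=False)

    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump({"version": manifest.version, "config": manifest.config,
                   "stages": manifest.stages}, fh, indent=2, default=str)
    return results
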