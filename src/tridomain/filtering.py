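"""Inclusion rules and within-domain proportions.

Two inclusion rules gate the analysis set: a per-sample sequencing-depth
floor (applied to the fungal ITS amplicon in the original design; the depth
default is therefore per-domain) and a per-genus prevalence + total-count
rule. All thresholds are inclusive ("at least" / "equal to or greater").

Proportions are computed within each amplicon on the full genus-aggregated
table *before* rare-genus removal, then rare genera are dropped for testing;
the applied order is recorded in the :class:`FilterReport`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import CountTable, Domain, ProportionTable

#: Per-domain default minimum reads per sample. The 200-read rule is stated
#: only for the ITS (fungal) amplicon.
DEFAULT_MIN_READS = {Domain.FUNGI: 200, Domain.BACTERIA: 0, Domain.ARCHAEA: 0}


@dataclass
class FilterReport:
    """Record of what was dropped and why; one triggering rule per item."""

    dropped_samples: list[tuple[str, str]] = field(default_factory=list)
    dropped_genera: list[tuple[str, str]] = field(default_factory=list)
    thresholds: dict = field(default_factory=dict)
    order: list[str] = field(default_factory=list)

    def merged_with(self, other: "FilterReport") -> "FilterReport":
        return FilterReport(
            dropped_samples=self.dropped_samples + other.dropped_samples,
            dropped_genera=self.dropped_genera + other.dropped_genera,
            thresholds={**self.thresholds, **other.thresholds},
            order=self.order + other.order,
        )


class EmptyResultError(ValueError):
    """A filter removed everything."""


def filter_samples_by_depth(
    counts: CountTable, min_reads: int | None = None
) -> tuple[CountTable, FilterReport]:
    """Keep samples whose total read count is >= ``min_reads`` (inclusive).

    ``min_reads=None`` uses the per-domain default (200 for fungi, 0
    otherwise). Sample order is preserved.
    """
    if min_reads is None:
        min_reads = DEFAULT_MIN_READS[counts.domain]
    sums = counts.df.sum(axis=0)
    keep = [s for s in counts.sample_ids if sums[s] >= min_reads]
    report = FilterReport(
        dropped_samples=[
            (s, f"total reads {int(sums[s])} < {min_reads}")
            for s in counts.sample_ids
            if sums[s] < min_reads
        ],
        thresholds={"min_reads": min_reads},
        order=["depth_filter"],
    )
    if not keep:
        raise EmptyResultError(
            f"depth filter at min_reads={min_reads} removed every sample"
        )
    return CountTable(domain=counts.domain, df=counts.df[keep]), report


def filter_genera(
    counts: CountTable, min_prevalence: int = 9, min_total: int = 10
) -> tuple[CountTable, FilterReport]:
    """Keep genera present (count > 0) in >= ``min_prevalence`` samples AND
    with total count >= ``min_total``; both boundaries inclusive."""
    mat = counts.df.to_numpy()
    prevalence = (mat > 0).sum(axis=1)
    totals = mat.sum(axis=1)
    keep, dropped = [], []
    for i, g in enumerate(counts.genus_ids):
        if prevalence[i] < min_prevalence:
            dropped.append((g, f"prevalence {int(prevalence[i])} < {min_prevalence}"))
        elif totals[i] < min_total:
            dropped.append((g, f"total count {int(totals[i])} < {min_total}"))
        else:
            keep.append(g)
    report = FilterReport(
        dropped_genera=dropped,
        thresholds={"min_prevalence": min_prevalence, "min_total": min_total},
        order=["genus_filter"],
    )
    return CountTable(domain=counts.domain, df=counts.df.loc[keep]), report


def to_proportions(counts: CountTable) -> ProportionTable:
    """Divide each sample column by its own sum; zero-depth samples stay
    all-zero and are flagged in ``empty_samples``."""
    mat = counts.df.to_numpy(dtype=float)
    sums = mat.sum(axis=0)
    empty = frozenset(
        s for j, s in enumerate(counts.sample_ids) if sums[j] == 0
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(sums > 0, mat / np.where(sums > 0, sums, 1.0), 0.0)
    df = pd.DataFrame(out, index=counts.genus_ids, columns=counts.sample_ids)
    return ProportionTable(domain=counts.domain, df=df, empty_samples=empty)


def prevalence_summary(
    fungi: CountTable | None = None,
    archaea: CountTable | None = None,
    *,
    methanogen_genus: str = "Methanobrevibacter",
    ammonia_oxidizer_genus: str = "Nitrososphaera",
    min_prevalence: int = 9,
) -> dict[str, float]:
    """Headline prevalence statistics of a genus x sample cohort.

    Computes, from raw (unfiltered) count tables, the summary counts a
    reader checks first: how many samples carry any archaeon, how many carry
    each of the two dominant archaeal genera and both at once, the sample
    prevalence (percent) of the three leading fungal genera, the number of
    fungal genera passing the prevalence rule, and the Spearman correlation
    between per-sample Ascomycota and Basidiomycota proportions (requires a
    taxonomy, so reported only when phylum rows can be inferred from genus
    ids prefixed conventions — callers pass phylum proportions directly via
    :func:`phylum_proportions` when available).
    """
    out: dict[str, float] = {}
    if archaea is not None:
        mat = archaea.df.to_numpy()
        positive = (mat.sum(axis=0) > 0).sum()
        out["archaea_positive_samples"] = int(positive)
        for key, genus in (
            ("methanobrevibacter_positive_samples", methanogen_genus),
            ("nitrososphaera_positive_samples", ammonia_oxidizer_genus),
        ):
            if genus in archaea.genus_ids:
                out[key] = int((archaea.df.loc[genus].to_numpy() > 0).sum())
        if methanogen_genus in archaea.genus_ids and ammonia_oxidizer_genus in archaea.genus_ids:
            both = (
                (archaea.df.loc[methanogen_genus].to_numpy() > 0)
                & (archaea.df.loc[ammonia_oxidizer_genus].to_numpy() > 0)
            ).sum()
            out["both_archaea_samples"] = int(both)
    if fungi is not None:
        n = len(fungi.sample_ids)
        mat = fungi.df.to_numpy()
        prev = (mat > 0).sum(axis=1)
        for genus in ("Saccharomyces", "Candida", "Cladosporium"):
            if genus in fungi.genus_ids:
                i = fungi.genus_ids.index(genus)
                out[f"{genus.lower()}_prevalence_pct"] = round(100.0 * prev[i] / n)
        out["fungal_genera_prevalence_ge_threshold"] = int((prev >= min_prevalence).sum())
    return out


def phylum_spearman(
    counts: CountTable, taxonomy_df: pd.DataFrame, phylum_a: str, phylum_b: str
) -> float:
    """Spearman rho between per-sample summed proportions of two phyla."""
    from scipy.stats import spearmanr

    props = to_proportions(counts)
    phyla = taxonomy_df.iloc[:, 0]
    a = props.df.loc[[g for g in props.genus_ids if phyla.get(g) == phylum_a]].sum(axis=0)
    b = props.df.loc[[g for g in props.genus_ids if phyla.get(g) == phylum_b]].sum(axis=0)
    rho = spearmanr(a.to_numpy(), b.to_numpy()).statistic
    return float(rho)
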