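"""Tabular data model and I/O for the tri-domain analysis.

All downstream stages operate on the validated containers defined here:
genus-by-sample read-count tables (one per Domain of life), ranked taxonomy
tables, within-domain proportion tables, and sample-by-nutrient inventories.
Files are plain UTF-8 TSV/CSV: first column is the feature id, first row the
sample ids; lines starting with ``#`` carry provenance and are ignored on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Default rank schema for genus lineages, top-down. Domain is table
#: metadata, not a rank.
DEFAULT_RANKS: tuple[str, ...] = ("Phylum", "Class", "Order", "Family", "Genus")

#: Sentinel used for missing rank labels. An unclassified rank never matches
#: any other rank label, including another "unclassified".
UNCLASSIFIED = "unclassified"


class Domain(str, Enum):
    """The three domains of life censused by the marker-gene surveys."""

    BACTERIA = "bacteria"
    ARCHAEA = "archaea"
    FUNGI = "fungi"


class ValidationError(ValueError):
    """An input table violates a structural invariant."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {what} id: {x!r}")
        seen.add(x)


@dataclass
class CountTable:
    """Genus x sample non-negative integer read counts for one domain.

    ``df`` is indexed by genus id with sample-id columns; order is preserved
    from the source file.
    """

    domain: Domain
    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.domain = Domain(self.domain)
        _check_unique(list(self.df.index), "genus")
        _check_unique(list(self.df.columns), "sample")
        vals = self.df.to_numpy()
        if vals.size and not np.issubdtype(vals.dtype, np.integer):
            # accept float frames that hold exact integers
            if not np.all(np.isfinite(vals)) or not np.all(vals == np.floor(vals)):
                bad = np.argwhere(~(np.isfinite(vals) & (vals == np.floor(vals))))[0]
                raise ValidationError(
                    f"non-integer count at genus {self.df.index[bad[0]]!r}, "
                    f"sample {self.df.columns[bad[1]]!r}"
                )
            self.df = self.df.astype(np.int64)
            vals = self.df.to_numpy()
        if vals.size and vals.min() < 0:
            bad = np.argwhere(vals < 0)[0]
            raise ValidationError(
                f"negative count at genus {self.df.index[bad[0]]!r}, "
                f"sample {self.df.columns[bad[1]]!r}"
            )

    @property
    def genus_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.df.to_numpy()

    def total_reads(self) -> int:
        return int(self.df.to_numpy().sum())


@dataclass
class TaxonomyTable:
    """Ranked lineage per genus.

    ``df`` is indexed by genus id with one column per rank (default
    Phylum..Genus). Missing labels are the ``unclassified`` sentinel. For a
    genus classified at the terminal rank, the terminal label equals the
    genus id.
    """

    df: pd.DataFrame
    ranks: tuple[str, ...] = DEFAULT_RANKS

    def __post_init__(self) -> None:
        _check_unique(list(self.df.index), "genus")
        if list(self.df.columns) != list(self.ranks):
            if self.df.shape[1] != len(self.ranks):
                raise ValidationError(
                    f"expected {len(self.ranks)} rank columns, got {self.df.shape[1]}"
                )
            self.df.columns = list(self.ranks)
        self.df = self.df.fillna(UNCLASSIFIED)
        for col in self.df.columns:
            self.df[col] = [
                UNCLASSIFIED if (not str(v).strip()) else str(v).strip()
                for v in self.df[col]
            ]
        for gid, row in self.df.iterrows():
            term = row.iloc[-1]
            if term != UNCLASSIFIED and term != gid:
                raise ValidationError(
                    f"terminal rank {term!r} does not equal genus id {gid!r}"
                )

    @property
    def n_ranks(self) -> int:
        return len(self.ranks)

    @property
    def genus_ids(self) -> list[str]:
        return list(self.df.index)

    def lineage(self, genus_id: str) -> list[str]:
        return list(self.df.loc[genus_id])


@dataclass
class ProportionTable:
    """Within-domain relative abundances on the CountTable axes.

    Each non-empty sample column sums to one; all-zero samples are kept as
    zero columns and listed in ``empty_samples``.
    """

    domain: Domain
    df: pd.DataFrame
    empty_samples: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.domain = Domain(self.domain)
        _check_unique(list(self.df.index), "genus")
        _check_unique(list(self.df.columns), "sample")
        vals = self.df.to_numpy(dtype=float)
        if vals.size:
            if vals.min() < 0 or vals.max() > 1 + 1e-12:
                raise ValidationError("proportions must lie in [0, 1]")
            sums = vals.sum(axis=0)
            for j, s in enumerate(self.df.columns):
                if s in self.empty_samples:
                    if sums[j] != 0:
                        raise ValidationError(f"sample {s!r} flagged empty but non-zero")
                elif abs(sums[j] - 1.0) > 1e-9:
                    raise ValidationError(
                        f"sample {s!r} proportions sum to {sums[j]!r}, expected 1"
                    )

    @property
    def genus_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.columns)


@dataclass
class NutrientTable:
    """Sample x nutrient inventory (one of the two diet instruments).

    ``inventory`` distinguishes the long-term food-frequency questionnaire
    ("usual") from the multi-day recall ("recent"). Constant-valued nutrient
    columns are flagged because they have no rank variation.
    """

    inventory: str  # "usual" | "recent"
    df: pd.DataFrame

    def __post_init__(self) -> None:
        if self.inventory not in ("usual", "recent"):
            raise ValidationError(f"inventory must be 'usual' or 'recent', got {self.inventory!r}")
        _check_unique(list(self.df.index), "sample")
        _check_unique(list(self.df.columns), "nutrient")
        vals = self.df.to_numpy(dtype=float)
        if vals.size and not np.all(np.isfinite(vals)):
            raise ValidationError("nutrient values must be finite")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def nutrient_ids(self) -> list[str]:
        return list(self.df.columns)

    @property
    def constant_nutrients(self) -> list[str]:
        vals = self.df.to_numpy(dtype=float)
        return [c for j, c in enumerate(self.df.columns) if np.ptp(vals[:, j]) == 0]


# ---------------------------------------------------------------------------
# I/O


def _provenance_lines(meta: Mapping[str, object] | None) -> str:
    if not meta:
        return ""
    return "".join(f"# {k}: {v}\n" for k, v in meta.items())


def _read_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def read_count_table(path, domain: Domain | str) -> CountTable:
    """Read a genus x sample TSV of integer read counts.

    Raises :class:`ValidationError` naming the offending genus/sample on
    non-integer or negative cells, and on duplicate ids.
    """
    raw = _read_tsv(path)
    _check_unique(list(raw.index), "genus")
    _check_unique(list(raw.columns), "sample")
    num = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=np.int64)
    for col in raw.columns:
        for gid, cell in raw[col].items():
            try:
                v = int(str(cell).strip())
            except (TypeError, ValueError):
                raise ValidationError(
                    f"non-integer cell {cell!r} at genus {gid!r}, sample {col!r}"
                ) from None
            if v < 0:
                raise ValidationError(
                    f"negative count {v} at genus {gid!r}, sample {col!r}"
                )
            num.at[gid, col] = v
    return CountTable(domain=Domain(domain), df=num)


def write_count_table(table: CountTable, path, provenance: Mapping[str, object] | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_provenance_lines(provenance))
        table.df.to_csv(fh, sep="\t")


def read_taxonomy(path, ranks: tuple[str, ...] = DEFAULT_RANKS) -> TaxonomyTable:
    """Read a genus-id + rank-columns TSV; blank cells become ``unclassified``."""
    raw = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str, keep_default_na=False)
    raw.index = raw.index.astype(str)
    raw.index.name = None
    raw = raw.replace("", UNCLASSIFIED)
    return TaxonomyTable(df=raw, ranks=ranks)


def write_taxonomy(tax: TaxonomyTable, path, provenance: Mapping[str, object] | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_provenance_lines(provenance))
        tax.df.to_csv(fh, sep="\t", index_label="genus_id")


def read_nutrients(path, inventory: str) -> NutrientTable:
    """Read a sample x nutrient CSV (samples as rows)."""
    df = pd.read_csv(path, index_col=0, comment="#")
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    return NutrientTable(inventory=inventory, df=df.astype(float))


def write_nutrients(nut: NutrientTable, path, provenance: Mapping[str, object] | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_provenance_lines(provenance))
        nut.df.to_csv(fh, index_label="sample_id")


def write_proportions(props: ProportionTable, path, provenance: Mapping[str, object] | None = None) -> None:
    meta = dict(provenance or {})
    if props.empty_samples:
        meta["empty_samples"] = ",".join(sorted(props.empty_samples))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_provenance_lines(meta))
        props.df.to_csv(fh, sep="\t")


# ---------------------------------------------------------------------------
# OTU -> genus aggregation


def aggregate_otus_to_genus(
    otu_counts: CountTable,
    otu_taxonomy: Mapping[str, Sequence[str]],
    min_otu_total: int = 5,
) -> CountTable:
    """Collapse an OTU x sample table to genus level.

    OTUs whose total read count across all samples is below ``min_otu_total``
    are dropped *before* aggregation (the inclusion rule is "a minimum of 5
    sequences detected across all samples"). Surviving OTUs are summed into
    their genus; lineages unclassified at genus aggregate into an
    ``Other_<lowest classified rank>`` bucket so they are retained rather
    than silently discarded.

    Parameters
    ----------
    otu_counts:
        OTU-level count table (feature ids are OTU ids).
    otu_taxonomy:
        Map OTU id -> ranked lineage (top-down, same length for all OTUs).
    """
    missing = [o for o in otu_counts.genus_ids if o not in otu_taxonomy]
    if missing:
        raise ValidationError(f"OTUs with no taxonomy entry: {missing[:5]}")
    totals = otu_counts.df.sum(axis=1)
    kept = [o for o in otu_counts.genus_ids if totals[o] >= min_otu_total]
    groups: dict[str, list[str]] = {}
    for o in kept:
        lineage = list(otu_taxonomy[o])
        genus = lineage[-1]
        if genus == UNCLASSIFIED:
            classified = [r for r in lineage if r != UNCLASSIFIED]
            label = f"Other_{classified[-1]}" if classified else "Other_unclassified"
        else:
            label = genus
        groups.setdefault(label, []).append(o)
    out = pd.DataFrame(
        {g: otu_counts.df.loc[members].sum(axis=0) for g, members in groups.items()}
    ).T
    out = out.astype(np.int64)
    out.columns = otu_counts.df.columns
    return CountTable(domain=otu_counts.domain, df=out)
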