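"""OTU-table container, I/O, filtering, rarefaction, and functional groups.

The :class:`OtuTable` is the currency of the whole pipeline: an OTU x sample
matrix of non-negative integer counts, per-sample metadata (habitat,
compartment, plant associate, month, location), and a Greengenes-style
seven-rank taxonomy string per OTU.

Filtering rules implemented here:

* organelle removal — OTUs whose lineage matches chloroplast or mitochondrial
  sequences are dropped before any analysis;
* rarefaction — uniform subsampling without replacement to a fixed depth
  (default 1,000 reads), dropping shallower samples, used for the
  diversity/distance branch of the pipeline;
* network prefilter — OTUs with fewer than 10 total counts or present in
  fewer than three samples are excluded before correlation estimation; the
  network branch runs on *un-rarefied* counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("otunet")

HABITATS = ("palsa", "bog", "fen")
COMPARTMENTS = ("phyllosphere", "rhizosphere", "peat")

#: Methanogen orders: union of the three orders known active at permafrost
#: sites with the extended eight-order list used for the putative-methanogen
#: census (both configurable via FunctionalGroupConfig).
METHANOGEN_ORDERS = (
    "Methanosarcinales",
    "Methanobacteriales",
    "Methanomicrobiales",
    "Methanococcales",
    "Methanopyrales",
    "Methanocellales",
    "Methanomassiliicoccales",
    "Candidatus Methanophagales",
)

METHANOTROPH_ORDERS = ("Methylacidiphilales",)

METHANOTROPH_FAMILIES = (
    "Beijerinckiaceae",
    "Hyphomicrobiaceae",
    "Methylocystaceae",
    "Crenotrichaceae",
    "Methylococcaceae",
)

_ORGANELLE_TOKENS = ("chloroplast", "mitochondria")

_META_COLUMNS = ("habitat", "compartment", "plant", "month", "location")


class OtuTableError(ValueError):
    """Raised when an OTU table violates its invariants."""


@dataclass
class OtuTable:
    """Samples x OTUs count matrix with metadata and taxonomy.

    Parameters
    ----------
    counts:
        DataFrame of non-negative integers, rows = OTU ids, columns = sample
        ids (classic OTU-table orientation).
    sample_meta:
        One row per sample (index = sample id) with at least the columns
        habitat, compartment, plant, month, location.
    taxonomy:
        Series mapping OTU id -> semicolon-delimited 7-rank lineage string
        ("k__...;p__...;c__...;o__...;f__...;g__...;s__...").
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame
    taxonomy: pd.Series

    def __post_init__(self) -> None:
        self.counts = self.counts.copy()
        arr = self.counts.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)) or np.isnan(arr).any():
                raise OtuTableError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
            arr = self.counts.to_numpy()
        if arr.size and arr.min() < 0:
            raise OtuTableError("counts must be non-negative")
        missing_meta = set(self.counts.columns) - set(self.sample_meta.index)
        extra_meta = set(self.sample_meta.index) - set(self.counts.columns)
        if missing_meta or extra_meta:
            raise OtuTableError(
                f"sample id mismatch: missing metadata for {sorted(missing_meta)}, "
                f"metadata without counts for {sorted(extra_meta)}"
            )
        missing_tax = set(self.counts.index) - set(self.taxonomy.index)
        extra_tax = set(self.taxonomy.index) - set(self.counts.index)
        if missing_tax or extra_tax:
            raise OtuTableError(
                f"OTU id mismatch: missing taxonomy for {sorted(missing_tax)}, "
                f"taxonomy without counts for {sorted(extra_tax)}"
            )
        # align order
        self.sample_meta = self.sample_meta.loc[list(self.counts.columns)]
        self.taxonomy = self.taxonomy.loc[list(self.counts.index)]
        for col, allowed in (("habitat", HABITATS), ("compartment", COMPARTMENTS)):
            if col in self.sample_meta.columns:
                unknown = set(self.sample_meta[col].unique()) - set(allowed)
                if unknown:
                    logger.warning("unknown %s levels preserved: %s", col, sorted(unknown))

    # -- basic views ------------------------------------------------------

    @property
    def otu_ids(self) -> list:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list:
        return list(self.counts.columns)

    @property
    def n_otus(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample closure: each column divided by its total."""
        totals = self.counts.sum(axis=0)
        if (totals == 0).any():
            bad = list(totals.index[totals == 0])
            raise OtuTableError(f"all-zero samples: {bad}")
        return self.counts / totals

    def subset_otus(self, otu_ids) -> "OtuTable":
        otu_ids = [o for o in self.otu_ids if o in set(otu_ids)]
        return OtuTable(
            self.counts.loc[otu_ids], self.sample_meta.copy(), self.taxonomy.loc[otu_ids]
        )

    def subset_samples(self, sample_ids) -> "OtuTable":
        sample_ids = [s for s in self.sample_ids if s in set(sample_ids)]
        return OtuTable(
            self.counts[sample_ids], self.sample_meta.loc[sample_ids], self.taxonomy.copy()
        )

    def __eq__(self, other) -> bool:  # value equality, used by round-trip tests
        if not isinstance(other, OtuTable):
            return NotImplemented
        return (
            self.counts.equals(other.counts)
            and self.sample_meta.equals(other.sample_meta)
            and self.taxonomy.equals(other.taxonomy)
        )


# -- I/O -------------------------------------------------------------------


def read_otu_table(counts_path, meta_path, tax_path) -> OtuTable:
    """Read counts, metadata and taxonomy TSVs into an :class:`OtuTable`.

    Counts TSV: OTUs as rows, samples as columns, first column = OTU id.
    Metadata TSV: one row per sample, first column = sample id.
    Taxonomy TSV: columns otu_id, taxonomy.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0, dtype=str)
    tax = pd.read_csv(tax_path, sep="\t", index_col=0)
    if tax.shape[1] < 1:
        raise OtuTableError("taxonomy TSV needs a lineage column")
    taxonomy = tax.iloc[:, 0].astype(str)
    taxonomy.name = "taxonomy"
    counts.index = counts.index.astype(str)
    meta.index = meta.index.astype(str)
    taxonomy.index = taxonomy.index.astype(str)
    counts.columns = counts.columns.astype(str)
    return OtuTable(counts, meta, taxonomy)


def write_otu_table(table: OtuTable, counts_path, meta_path, tax_path) -> None:
    table.counts.rename_axis("otu_id").to_csv(counts_path, sep="\t")
    table.sample_meta.rename_axis("sample_id").to_csv(meta_path, sep="\t")
    table.taxonomy.rename("taxonomy").rename_axis("otu_id").to_csv(tax_path, sep="\t")


# -- filtering -------------------------------------------------------------


def remove_organelles(table: OtuTable) -> OtuTable:
    """Drop OTUs whose lineage matches chloroplast or mitochondrial sequences.

    Matching is a case-insensitive substring test for "chloroplast" /
    "mitochondria" anywhere in the lineage string.
    """
    lineages = table.taxonomy.str.lower()
    is_organelle = lineages.str.contains(_ORGANELLE_TOKENS[0]) | lineages.str.contains(
        _ORGANELLE_TOKENS[1]
    )
    dropped = list(table.taxonomy.index[is_organelle])
    if dropped:
        logger.info("remove_organelles: dropped %d OTUs: %s", len(dropped), dropped[:20])
    keep = [o for o in table.otu_ids if o not in set(dropped)]
    if not keep:
        logger.warning("remove_organelles: no OTUs remain")
    return table.subset_otus(keep)


def rarefy(table: OtuTable, depth: int = 1000, seed: int | None = None) -> OtuTable:
    """Subsample each sample, without replacement, to exactly ``depth`` reads.

    Samples with fewer than ``depth`` reads are dropped (and logged): equal
    depth is the point of rarefaction. Deterministic given ``seed``.
    """
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be positive, got {depth}")
    rng = np.random.default_rng(seed)
    totals = table.counts.sum(axis=0)
    kept, cols = [], {}
    for s in table.sample_ids:
        if totals[s] < depth:
            logger.info("rarefy: dropping sample %s (total %d < %d)", s, totals[s], depth)
            continue
        col = table.counts[s].to_numpy()
        if totals[s] == depth:
            cols[s] = col
        else:
            # multivariate hypergeometric draw == uniform subsample w/o replacement
            cols[s] = rng.multivariate_hypergeometric(col, depth)
        kept.append(s)
    if not kept:
        raise OtuTableError(f"no sample reaches rarefaction depth {depth}")
    counts = pd.DataFrame(cols, index=table.counts.index, columns=kept, dtype=np.int64)
    return OtuTable(counts, table.sample_meta.loc[kept], table.taxonomy.copy())


def filter_for_networks(
    table: OtuTable, min_total: int = 10, min_samples: int = 3
) -> OtuTable:
    """Network prefilter: keep OTUs with total >= min_total AND present
    (count > 0) in >= min_samples samples. Applied to un-rarefied counts."""
    totals = table.counts.sum(axis=1)
    presence = (table.counts > 0).sum(axis=1)
    keep = table.counts.index[(totals >= min_total) & (presence >= min_samples)]
    n_drop = table.n_otus - len(keep)
    if n_drop:
        logger.info("filter_for_networks: removed %d of %d OTUs", n_drop, table.n_otus)
    return table.subset_otus(list(keep))


# -- functional groups -----------------------------------------------------


@dataclass
class FunctionalGroupConfig:
    """Lineage name lists that define the methane-cycling functional groups."""

    methanogen_orders: tuple = METHANOGEN_ORDERS
    methanotroph_orders: tuple = METHANOTROPH_ORDERS
    methanotroph_families: tuple = METHANOTROPH_FAMILIES

    def __post_init__(self) -> None:
        for name in ("methanogen_orders", "methanotroph_orders", "methanotroph_families"):
            vals = getattr(self, name)
            if not vals or len(set(vals)) != len(vals):
                raise ValueError(f"{name} must be non-empty and unique")


def _rank(lineage: str, prefix: str) -> str:
    for part in lineage.split(";"):
        part = part.strip()
        if part.lower().startswith(prefix):
            return part[len(prefix):].strip()
    return ""


def assign_functional_groups(
    table: OtuTable, config: FunctionalGroupConfig | None = None
) -> pd.Series:
    """Label each OTU methanogen / methanotroph / other from its lineage.

    Methanogen: order in ``methanogen_orders``. Methanotroph: order in
    ``methanotroph_orders`` or family in ``methanotroph_families``. An OTU
    matching both is a configuration error (lists must be disjoint).
    """
    config = config or FunctionalGroupConfig()
    mg_orders = {o.lower() for o in config.methanogen_orders}
    mt_orders = {o.lower() for o in config.methanotroph_orders}
    mt_families = {f.lower() for f in config.methanotroph_families}
    labels = {}
    for otu, lineage in table.taxonomy.items():
        order = _rank(lineage, "o__").lower()
        family = _rank(lineage, "f__").lower()
        is_mg = order in mg_orders
        is_mt = order in mt_orders or family in mt_families
        if is_mg and is_mt:
            raise ValueError(
                f"OTU {otu} matches both methanogen and methanotroph lists; "
                "the configured lists must be disjoint"
            )
        labels[otu] = "methanogen" if is_mg else ("methanotroph" if is_mt else "other")
    return pd.Series(labels, name="functional_group").loc[table.otu_ids]


# -- grouping --------------------------------------------------------------


@dataclass
class GroupedTables:
    """Per-group sub-tables plus per-group mean relative abundances."""

    tables: dict = field(default_factory=dict)  # group key tuple -> OtuTable
    group_means: pd.DataFrame | None = None  # groups x OTUs mean rel. abundance


def split_by_group(table: OtuTable, keys: list[str]) -> GroupedTables:
    """Partition samples by the observed combinations of metadata ``keys``.

    Also computes each group's mean OTU relative-abundance vector (mean of
    per-sample closed proportions), used for node sizing and for the
    abundance-vs-importance community profiles.
    """
    for k in keys:
        if k not in table.sample_meta.columns:
            raise KeyError(f"unknown metadata field {k!r}")
    rel = table.relative_abundance()
    grouped = GroupedTables()
    means = {}
    meta = table.sample_meta
    for key, sub in meta.groupby(list(keys), sort=True, observed=True):
        if not isinstance(key, tuple):
            key = (key,)
        samples = list(sub.index)
        grouped.tables[key] = table.subset_samples(samples)
        means["|".join(str(k) for k in key)] = rel[samples].mean(axis=1)
    grouped.group_means = pd.DataFrame(means).T
    grouped.group_means.index.name = "group"
    return grouped
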