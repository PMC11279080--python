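"""Community count tables: I/O, validation, rarefaction, and taxon filters.

The central container is :class:`CountTable`, a samples x taxa matrix of
non-negative integer read counts backed by a :class:`pandas.DataFrame`.
On-disk convention follows the common amplicon-table layout (taxa as rows,
first column the ASV id); in memory everything is samples x taxa.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: lineage ranks, most to least inclusive
RANKS = ("domain", "phylum", "class", "order", "family", "genus")

#: lineages removed from the protist table before analysis
DEFAULT_NONTARGET = ("Metazoa", "Opisthokonta", "Rhodophyta", "Streptophyta")

#: label under which taxa unassigned at the aggregation rank are pooled
UNASSIGNED_LABEL = "unassigned"


class CountTable:
    """Sample-by-taxon matrix of non-negative integer counts.

    Parameters
    ----------
    data:
        DataFrame with sample ids as the index and taxon ids as columns.
        Values must be non-negative integers; floats are accepted only when
        integral (as produced by some writers) and are cast to int64.
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if data.columns.has_duplicates:
            dups = data.columns[data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate taxon ids: {dups}")
        values = data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            bad = _first_offending_cell(data, lambda v: not _is_number(v))
            raise ValueError(f"non-numeric count at sample={bad[0]!r}, taxon={bad[1]!r}")
        if values.size:
            if np.any(values < 0):
                bad = _first_offending_cell(data, lambda v: v < 0)
                raise ValueError(f"negative count at sample={bad[0]!r}, taxon={bad[1]!r}")
            if not np.issubdtype(values.dtype, np.integer) and np.any(values % 1 != 0):
                bad = _first_offending_cell(data, lambda v: v % 1 != 0)
                raise ValueError(f"non-integer count at sample={bad[0]!r}, taxon={bad[1]!r}")
        self.data = data.astype(np.int64)

    # -- basic protocol ----------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def totals(self) -> pd.Series:
        """Per-sample read totals."""
        return self.data.sum(axis=1)

    def __eq__(self, other) -> bool:
        return isinstance(other, CountTable) and self.data.equals(other.data)

    def __repr__(self) -> str:
        return f"CountTable({self.shape[0]} samples x {self.shape[1]} taxa)"

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def read_tsv(cls, path, orientation: str = "taxa-as-rows") -> "CountTable":
        """Read a delimited count matrix and normalize to samples x taxa."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        if orientation == "taxa-as-rows":
            df = df.T
        elif orientation != "samples-as-rows":
            raise ValueError(f"unknown orientation {orientation!r}")
        return cls(df)

    def to_tsv(self, path, orientation: str = "taxa-as-rows") -> None:
        df = self.data.T if orientation == "taxa-as-rows" else self.data
        label = "ASV_ID" if orientation == "taxa-as-rows" else "Sample_ID"
        df.to_csv(path, sep="\t", index_label=label)


class TaxonomyTable:
    """Taxon id -> ranked lineage (domain ... genus).

    Missing or empty rank values are normalized to ``"unassigned"``.
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate taxon ids in taxonomy: {dups}")
        missing = [r for r in RANKS if r not in data.columns]
        if missing:
            raise ValueError(f"taxonomy missing rank columns: {missing}")
        df = data.loc[:, list(RANKS)].copy()
        df = df.fillna(UNASSIGNED_LABEL).astype(str)
        df = df.where(df.apply(lambda col: col.str.strip() != ""), UNASSIGNED_LABEL)
        self.data = df

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.index)

    def lineage(self, taxon_id: str) -> dict[str, str]:
        return self.data.loc[taxon_id].to_dict()

    @classmethod
    def read_tsv(cls, path) -> "TaxonomyTable":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="ASV_ID")


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def _first_offending_cell(df: pd.DataFrame, predicate):
    for sample in df.index:
        for taxon in df.columns:
            try:
                if predicate(df.at[sample, taxon]):
                    return sample, taxon
            except TypeError:
                return sample, taxon
    raise AssertionError("no offending cell found")  # pragma: no cover


# ---------------------------------------------------------------------------
# transformations


def rarefy(table: CountTable, depth: int, seed) -> CountTable:
    """Subsample each sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped (and logged),
    mirroring standard practice of rarefying to a common minimum depth.
    The draw is multivariate hypergeometric, seeded and deterministic.
    """
    if depth < 1:
        raise ValueError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = table.totals()
    kept = [s for s in table.sample_ids if totals[s] >= depth]
    dropped = [s for s in table.sample_ids if totals[s] < depth]
    if not kept:
        raise ValueError(f"no samples retained at rarefaction depth {depth}")
    if dropped:
        logger.info("rarefy: dropped %d samples below depth %d: %s", len(dropped), depth, dropped)
    out = np.empty((len(kept), table.shape[1]), dtype=np.int64)
    for i, s in enumerate(kept):
        counts = table.data.loc[s].to_numpy()
        if counts.sum() == depth:
            out[i] = counts
        else:
            out[i] = rng.multivariate_hypergeometric(counts, depth)
    return CountTable(pd.DataFrame(out, index=kept, columns=table.taxon_ids))


def filter_nontarget_protists(
    table: CountTable,
    taxonomy: TaxonomyTable,
    nontarget: tuple[str, ...] = DEFAULT_NONTARGET,
    unassigned_rank: str = "phylum",
) -> CountTable:
    """Drop taxa from non-target lineages or unassigned at ``unassigned_rank``.

    A taxon is removed when any rank of its lineage matches a name in
    ``nontarget`` (by default Metazoa, Opisthokonta, Rhodophyta,
    Streptophyta) or when its ``unassigned_rank`` entry is "unassigned".
    Column order of the retained taxa is preserved.
    """
    if unassigned_rank not in RANKS:
        raise ValueError(f"unknown rank {unassigned_rank!r}")
    missing = [t for t in table.taxon_ids if t not in taxonomy.data.index]
    if missing:
        raise KeyError(f"taxa missing from taxonomy: {missing}")
    nontarget_set = set(nontarget)
    keep = []
    for t in table.taxon_ids:
        lineage = taxonomy.data.loc[t]
        if set(lineage) & nontarget_set:
            continue
        if lineage[unassigned_rank] == UNASSIGNED_LABEL:
            continue
        keep.append(t)
    removed = table.shape[1] - len(keep)
    if removed:
        logger.info("filter_nontarget_protists: removed %d taxa", removed)
    return CountTable(table.data.loc[:, keep])


def prevalence_abundance_filter(
    table: CountTable, min_months: int = 7, min_total_reads: int = 12
) -> CountTable:
    """Keep taxa present in >= ``min_months`` samples with total >= ``min_total_reads``.

    Intended for one site's monthly series ahead of network construction:
    a taxon survives only if it is detected in at least ``min_months`` of the
    samples *and* sums to at least ``min_total_reads`` reads. Both bounds are
    inclusive.
    """
    present = (table.data > 0).sum(axis=0)
    total = table.data.sum(axis=0)
    keep = table.data.columns[(present >= min_months) & (total >= min_total_reads)]
    return CountTable(table.data.loc[:, keep])


def aggregate_relative_abundance(
    table: CountTable, taxonomy: TaxonomyTable, rank: str
) -> pd.DataFrame:
    """Sum counts by lineage label at ``rank`` and convert to proportions.

    Returns a samples x labels DataFrame whose rows sum to 1. Taxa whose
    lineage is unassigned at ``rank`` are pooled under "unassigned".
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    missing = [t for t in table.taxon_ids if t not in taxonomy.data.index]
    if missing:
        raise KeyError(f"taxa missing from taxonomy: {missing}")
    totals = table.totals()
    zero = totals[totals == 0].index.tolist()
    if zero:
        raise ValueError(f"zero-total samples cannot be normalized: {zero}")
    labels = taxonomy.data.loc[table.taxon_ids, rank]
    grouped = table.data.T.groupby(labels.values, sort=True).sum().T
    return grouped.div(totals, axis=0)
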