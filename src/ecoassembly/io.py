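"""Tabular and tree I/O plus depth normalisation (rarefaction).

The universal input is an OTU count table: non-negative integer read counts
for each sample × OTU combination.  Tables are stored samples-as-rows
internally; on disk either orientation is accepted (auto-detected, with an
explicit override).  Trees are Newick files whose tips are OTU identifiers;
patristic distances between tips feed the phylogenetic turnover metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import skbio


class OtuTableError(ValueError):
    """Raised for malformed OTU tables or contract violations."""


@dataclass
class OtuTable:
    """Integer count matrix, samples × OTUs.

    Parameters
    ----------
    counts : pandas.DataFrame
        Non-negative integer counts with sample identifiers as the index
        and OTU identifiers as the columns.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise OtuTableError(f"duplicate sample identifiers: {dups}")
        if df.columns.duplicated().any():
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise OtuTableError(f"duplicate OTU identifiers: {dups}")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            # accept float input only if exactly integral
            if not np.all(np.isfinite(arr)) or np.any(arr != np.floor(arr)):
                bad = np.argwhere(arr != np.floor(arr))
                r, c = bad[0]
                raise OtuTableError(
                    f"non-integer count at sample {df.index[r]!r}, OTU {df.columns[c]!r}"
                )
            df = df.astype(np.int64)
        if (arr < 0).any():
            bad = np.argwhere(arr < 0)
            r, c = bad[0]
            raise OtuTableError(
                f"negative count at sample {df.index[r]!r}, OTU {df.columns[c]!r}"
            )
        object.__setattr__(self, "counts", df.astype(np.int64))

    # -- convenience accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    @property
    def matrix(self) -> np.ndarray:
        """Counts as an int64 array (samples × OTUs)."""
        return self.counts.to_numpy()

    def sample_sums(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def otu_sums(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_samples(self, sample_ids) -> "OtuTable":
        return OtuTable(self.counts.loc[list(sample_ids)])

    def drop_empty_otus(self) -> "OtuTable":
        keep = self.counts.sum(axis=0) > 0
        return OtuTable(self.counts.loc[:, keep])

    def __eq__(self, other) -> bool:
        if not isinstance(other, OtuTable):
            return NotImplemented
        return self.counts.equals(other.counts)


@dataclass
class SampleMetadata:
    """Sample → (region, site, zone) mapping."""

    table: pd.DataFrame  # index = sample_id; columns include region, site, zone

    REQUIRED = ("region", "site", "zone")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise OtuTableError(f"metadata missing columns: {missing}")
        if self.table.index.duplicated().any():
            raise OtuTableError("duplicate sample identifiers in metadata")

    def zone_of(self, sample_ids) -> pd.Series:
        """Resolve each sample to exactly one zone; missing samples are a hard error."""
        missing = [s for s in sample_ids if s not in self.table.index]
        if missing:
            raise OtuTableError(f"samples absent from metadata: {missing}")
        return self.table.loc[list(sample_ids), "zone"]

    def samples_in_zone(self, zone: str) -> list:
        return list(self.table.index[self.table["zone"] == zone])

    @property
    def zones(self) -> list:
        return sorted(self.table["zone"].unique())


def read_otu_table(path, orientation: str = "auto") -> OtuTable:
    """Read a tab-separated OTU table.

    Parameters
    ----------
    path : str or Path
        TSV file with one header row and one identifier column.
    orientation : {"auto", "samples_rows", "otus_rows"}
        On-disk orientation.  ``auto`` treats rows as samples unless there
        are many more rows than columns (the common OTUs-as-rows layout).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if orientation not in ("auto", "samples_rows", "otus_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if orientation == "auto":
        # heuristic: OTU tables usually have far more OTUs than samples
        orientation = "otus_rows" if df.shape[0] > 4 * df.shape[1] else "samples_rows"
    if orientation == "otus_rows":
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return OtuTable(df)


def write_otu_table(table: OtuTable, path) -> None:
    table.counts.to_csv(path, sep="\t", index_label="sample_id")


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.table.to_csv(path, sep="\t", index_label="sample_id")


def read_taxonomy(path) -> pd.DataFrame:
    """OTU → ranked lineage table; missing ranks left as empty strings."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str).fillna("")
    df.index = df.index.astype(str)
    return df


def rarefy(table: OtuTable, depth: int, seed, drop_empty: bool = True) -> OtuTable:
    """Subsample every sample to ``depth`` reads without replacement.

    Each sample is an independent multivariate-hypergeometric draw, so the
    result is one random rarefaction, bit-reproducible under a fixed seed.
    OTU columns left with zero total are dropped unless ``drop_empty=False``.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    sums = table.sample_sums()
    short = sums[sums < depth]
    if len(short):
        raise OtuTableError(
            "samples shallower than the rarefaction depth "
            f"{depth}: {dict(short)}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.matrix)
    for i, row in enumerate(table.matrix):
        total = int(row.sum())
        if total == depth:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(row, depth)
    df = pd.DataFrame(out, index=table.counts.index, columns=table.counts.columns)
    result = OtuTable(df)
    return result.drop_empty_otus() if drop_empty else result


def read_tree(path_or_str) -> skbio.TreeNode:
    """Read a rooted Newick tree with branch lengths.

    Returns a ``skbio.TreeNode``; tip-to-tip (patristic) distances are
    available via :func:`patristic_distances`.  Unlabeled tips are a hard
    error because they cannot be joined against OTU identifiers.
    """
    tree = skbio.TreeNode.read(
        str(path_or_str) if hasattr(path_or_str, "exists") else _as_source(path_or_str)
    )
    names = [t.name for t in tree.tips()]
    if any(n is None or n == "" for n in names):
        raise ValueError("tree contains unlabeled tips")
    if len(set(names)) != len(names):
        raise ValueError("tree tip labels are not unique")
    return tree


def _as_source(s):
    import io as _io

    if isinstance(s, str) and s.lstrip().startswith("("):
        return _io.StringIO(s)
    return str(s)


def patristic_distances(tree: skbio.TreeNode, otu_ids=None):
    """Patristic distance matrix over tips, optionally restricted to ``otu_ids``.

    Tips without a matching OTU id (and vice versa) are reported with a
    warning; the returned matrix covers the intersection, ordered as
    ``otu_ids``.
    """
    dm = tree.tip_tip_distances()
    tips = set(dm.ids)
    if otu_ids is None:
        return pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids)
    otu_ids = list(otu_ids)
    missing = [o for o in otu_ids if o not in tips]
    if missing:
        warnings.warn(
            f"{len(missing)} OTU ids absent from the tree (e.g. {missing[:5]}); "
            "they are excluded from phylogenetic metrics"
        )
    keep = [o for o in otu_ids if o in tips]
    if not keep:
        raise ValueError("no overlap between table OTUs and tree tips")
    full = pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids)
    return full.loc[keep, keep]
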