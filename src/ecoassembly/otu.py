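"""OTU tables, environment tables and their plain-text I/O.

The canonical in-memory orientation is samples x taxa; readers normalise
whichever dialect the file uses.  Counts are non-negative integers
throughout; rarefaction subsamples reads without replacement
(multivariate hypergeometric), so a rarefied row sums exactly to the
requested depth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "OtuTable",
    "EnvTable",
    "read_otu_table",
    "write_otu_table",
    "read_env_table",
    "write_env_table",
    "rarefy",
    "filter_prevalence",
]


@dataclass
class OtuTable:
    """A samples x taxa count matrix with optional per-taxon taxonomy.

    Parameters
    ----------
    data:
        DataFrame indexed by sample id with taxon ids as columns;
        non-negative integer counts.
    taxonomy:
        Optional Series mapping taxon id to a lineage string.
    """

    data: pd.DataFrame
    taxonomy: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate taxon ids: {dups}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("counts must be numeric")
        if np.any(values < 0):
            raise ValueError("counts must be non-negative")
        if not np.allclose(values, np.round(values)):
            raise ValueError("counts must be integers")
        self.data = self.data.astype(np.int64)
        if self.taxonomy is not None:
            self.taxonomy = self.taxonomy.reindex(self.data.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    def relative_abundance(self) -> pd.DataFrame:
        totals = self.data.sum(axis=1)
        if (totals == 0).any():
            bad = totals.index[totals == 0].tolist()
            raise ValueError(f"all-zero sample(s): {bad}")
        return self.data.div(totals, axis=0)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OtuTable):
            return NotImplemented
        return self.data.equals(other.data)


@dataclass
class EnvTable:
    """Per-sample environmental variables plus categorical grouping labels.

    ``data`` holds the numeric variables (one row per sample); ``grouping``
    holds the categorical columns (season, site, ...) on the same index.
    """

    data: pd.DataFrame
    grouping: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate sample ids in environment table")
        if len(self.grouping) and not self.grouping.index.equals(self.data.index):
            raise ValueError("grouping index must match sample ids")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)


def _resolve_sep(path: str | Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    suffix = Path(path).suffix.lower()
    return "," if suffix == ".csv" else "\t"


def read_otu_table(
    path: str | Path,
    orientation: str = "taxa_as_rows",
    sep: str | None = None,
    taxonomy_column: str | None = None,
) -> OtuTable:
    """Read a tab- or comma-separated OTU table.

    ``orientation`` names what the file's *rows* are ("taxa_as_rows", the
    common QIIME-style dialect, or "samples_as_rows"); the returned table is
    always samples x taxa.  ``taxonomy_column`` optionally names a trailing
    lineage column in taxa-as-rows files.
    """
    if orientation not in ("taxa_as_rows", "samples_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = _resolve_sep(path, sep)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, comment="#")
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    taxonomy = None
    if taxonomy_column is not None:
        if taxonomy_column not in df.columns:
            raise ValueError(f"taxonomy column {taxonomy_column!r} not in {path}")
        taxonomy = df.pop(taxonomy_column)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        if converted.isna().any() and not df[col].isna().any():
            row = df.index[converted.isna()][0]
            raise ValueError(f"non-numeric cell at row {row!r}, column {col!r} in {path}")
        df[col] = converted
    if df.isna().any().any():
        raise ValueError(f"missing values in {path}")
    if orientation == "taxa_as_rows":
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return OtuTable(df, taxonomy=taxonomy)


def write_otu_table(
    table: OtuTable,
    path: str | Path,
    orientation: str = "taxa_as_rows",
    sep: str | None = None,
) -> None:
    sep = _resolve_sep(path, sep)
    df = table.data.T if orientation == "taxa_as_rows" else table.data
    df.to_csv(path, sep=sep)


def read_env_table(
    path: str | Path,
    group_columns: tuple[str, ...] = ("season", "site"),
    sep: str | None = None,
) -> EnvTable:
    """Read a metadata CSV: one row per sample, numeric variables plus
    categorical grouping columns named in ``group_columns``."""
    sep = _resolve_sep(path, sep)
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    groups = df[[c for c in group_columns if c in df.columns]].astype(str)
    data = df.drop(columns=groups.columns)
    data = data.apply(pd.to_numeric)
    return EnvTable(data, groups)


def write_env_table(env: EnvTable, path: str | Path, sep: str | None = None) -> None:
    sep = _resolve_sep(path, sep)
    pd.concat([env.grouping, env.data], axis=1).to_csv(path, sep=sep)


def rarefy(
    table: OtuTable,
    depth: int,
    seed: int,
    drop_small: bool = False,
) -> OtuTable:
    """Subsample every sample to ``depth`` reads without replacement.

    Samples with fewer than ``depth`` reads raise unless ``drop_small``,
    in which case they are dropped with a warning.  Reproducible under
    ``seed``.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    totals = table.data.sum(axis=1)
    small = totals.index[totals < depth]
    if len(small):
        if not drop_small:
            raise ValueError(
                f"samples below depth {depth}: {list(small)}; pass drop_small=True to drop"
            )
        warnings.warn(f"dropping {len(small)} sample(s) below depth {depth}")
    keep = totals.index[totals >= depth]
    rng = np.random.default_rng(seed)
    rows = {}
    for sid in keep:
        row = table.data.loc[sid].to_numpy()
        if row.sum() == depth:
            rows[sid] = row
        else:
            rows[sid] = rng.multivariate_hypergeometric(row, depth)
    out = pd.DataFrame.from_dict(rows, orient="index", columns=table.data.columns)
    return OtuTable(out.loc[keep], taxonomy=table.taxonomy)


def filter_prevalence(table: OtuTable, min_total: int = 10) -> OtuTable:
    """Keep taxa whose total count across all samples is strictly greater
    than ``min_total`` (default 10).  The sample set is unchanged."""
    totals = table.data.sum(axis=0)
    keep = totals.index[totals > min_total]
    taxonomy = table.taxonomy.loc[keep] if table.taxonomy is not None else None
    return OtuTable(table.data[keep], taxonomy=taxonomy)
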