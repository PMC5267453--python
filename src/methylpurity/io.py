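"""Data containers and delimited-text readers/writers.

The package works on methylation *beta values*: per-CpG fractions in
[0, 1] (methylated signal over total signal), arranged as a sites x
samples matrix.  Files are plain delimited text: first column CpG
identifiers, header row sample identifiers, ``NA`` (configurable) for
missing entries.  Lines starting with ``#`` are treated as comments so
that tables written by this package (which carry a provenance header)
round-trip through the readers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "BetaMatrix",
    "SampleGroups",
    "PurityTable",
    "read_beta_matrix",
    "read_purity_table",
    "read_idmc_table",
    "write_table",
]


def _check_unique(ids, what: str) -> None:
    counts = pd.Index(ids).value_counts()
    dups = counts[counts > 1]
    if len(dups):
        raise ValueError(f"duplicate {what} id(s): {', '.join(map(str, dups.index[:5]))}")


@dataclass
class BetaMatrix:
    """Sites-by-samples matrix of methylation beta values.

    ``values`` is a float DataFrame indexed by CpG site id with sample
    ids as columns; missing entries are NaN.  All non-missing values
    must lie in [0, 1] (0 and 1 are legal: the arcsine transform is
    finite at the boundaries, so no clipping is performed).
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        _check_unique(self.values.index, "site")
        _check_unique(self.values.columns, "sample")
        v = self.values.to_numpy()
        bad = (v < 0) | (v > 1)
        if np.any(bad):
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"beta value out of [0, 1] at site {self.values.index[i]!r}, "
                f"sample {self.values.columns[j]!r}: {v[i, j]}"
            )

    @property
    def site_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_sites(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids) -> pd.DataFrame:
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise KeyError(f"sample id(s) not in matrix: {missing[:5]}")
        return self.values[list(sample_ids)]


@dataclass
class SampleGroups:
    """Tumor / normal partition of sample ids.

    ``normal_ids`` may be empty for control-free workflows.
    """

    tumor_ids: list = field(default_factory=list)
    normal_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.tumor_ids = list(self.tumor_ids)
        self.normal_ids = list(self.normal_ids)
        _check_unique(self.tumor_ids, "tumor sample")
        _check_unique(self.normal_ids, "normal sample")
        overlap = set(self.tumor_ids) & set(self.normal_ids)
        if overlap:
            raise ValueError(f"sample(s) in both groups: {sorted(overlap)[:5]}")

    @property
    def n_tumor(self) -> int:
        return len(self.tumor_ids)

    @property
    def n_normal(self) -> int:
        return len(self.normal_ids)

    def validate_against(self, beta: BetaMatrix) -> None:
        known = set(beta.sample_ids)
        unknown = [s for s in self.tumor_ids + self.normal_ids if s not in known]
        if unknown:
            raise KeyError(f"group sample id(s) absent from beta matrix: {unknown[:5]}")


@dataclass
class PurityTable:
    """Per-tumor-sample purity fraction, lambda in (0, 1]."""

    purity: pd.Series

    def __post_init__(self) -> None:
        self.purity = self.purity.astype(float)
        _check_unique(self.purity.index, "sample")
        bad = self.purity[(self.purity <= 0) | (self.purity > 1)]
        if len(bad):
            raise ValueError(
                f"purity out of (0, 1] for sample(s) {list(bad.index[:5])}: {list(bad.values[:5])}"
            )

    def __getitem__(self, sample_id) -> float:
        return float(self.purity[sample_id])

    def __len__(self) -> int:
        return len(self.purity)

    def for_samples(self, sample_ids) -> np.ndarray:
        missing = [s for s in sample_ids if s not in self.purity.index]
        if missing:
            raise KeyError(f"no purity for sample(s): {missing[:5]}")
        return self.purity[list(sample_ids)].to_numpy()


def _sep(dialect: str) -> str:
    try:
        return {"tsv": "\t", "csv": ","}[dialect]
    except KeyError:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'tsv' or 'csv'") from None


def read_beta_matrix(path, dialect: str = "tsv", missing_token: str = "NA") -> BetaMatrix:
    """Read a beta matrix from delimited text.

    First column holds site ids, header row holds sample ids, cells are
    numeric or ``missing_token``.  Values outside [0, 1], duplicate ids
    and non-numeric cells raise ``ValueError`` naming the offender.
    """
    df = pd.read_csv(
        path,
        sep=_sep(dialect),
        index_col=0,
        na_values=[missing_token],
        keep_default_na=False,
        comment="#",
    )
    for col in df.columns:
        if df[col].dtype == object:
            coerced = pd.to_numeric(df[col], errors="coerce")
            newly_bad = coerced.isna() & df[col].notna()
            if newly_bad.any():
                row = df.index[np.argmax(newly_bad.to_numpy())]
                raise ValueError(
                    f"non-numeric cell at site {row!r}, sample {col!r}: "
                    f"{df.loc[row, col]!r}"
                )
            df[col] = coerced
    return BetaMatrix(df)


def read_purity_table(path, dialect: str = "tsv") -> PurityTable:
    """Read a two-column (sample_id, purity) table."""
    df = pd.read_csv(path, sep=_sep(dialect), index_col=0, comment="#")
    if df.shape[1] < 1:
        raise ValueError(f"purity table {path} needs sample_id and purity columns")
    return PurityTable(df.iloc[:, 0])


def read_idmc_table(path, dialect: str = "tsv") -> pd.DataFrame:
    """Read an iDMC list: site_id plus a direction column ('hyper'/'hypo')."""
    df = pd.read_csv(path, sep=_sep(dialect), comment="#")
    if "site_id" not in df.columns or "direction" not in df.columns:
        raise ValueError(f"iDMC table {path} must have 'site_id' and 'direction' columns")
    bad = set(df["direction"]) - {"hyper", "hypo"}
    if bad:
        raise ValueError(f"invalid direction value(s): {sorted(bad)}")
    _check_unique(df["site_id"], "iDMC site")
    return df


def write_table(rows: pd.DataFrame, path, dialect: str = "tsv", header_comment: str | None = None) -> None:
    """Write a result table as delimited text with a header row.

    ``header_comment`` (optional, may span lines) is emitted as ``#``
    comment lines before the header so reads skip it; the table
    round-trips through ``pd.read_csv(..., comment='#')``.
    """
    sep = _sep(dialect)
    with open(path, "w") as fh:
        if header_comment:
            for line in str(header_comment).splitlines():
                fh.write(f"# {line}\n")
        rows.to_csv(fh, sep=sep, index=False, lineterminator="\n")
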