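"""Specimen × feature count matrices and compositional utilities.

Raw specimen-ASV counts are collapsed to specimen-phylotype counts via an
ASV → phylotype assignment; reads of unassigned ASVs land in an explicit
``unclassified`` column so per-specimen totals are conserved exactly and the
assigned fraction stays auditable.  Before distance calculations, counts are
normalized to a fixed pseudo-count depth (default 10,000 reads/specimen;
kept real-valued — no rounding rule is imposed), and Bray-Curtis
dissimilarities are computed with scipy's pairwise distance machinery.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import FormatError, UsageError

__all__ = [
    "CountTable",
    "UNCLASSIFIED",
    "read_asv_counts",
    "phylotype_counts",
    "assigned_fraction",
    "normalize_counts",
    "bray_curtis",
]

logger = logging.getLogger(__name__)

UNCLASSIFIED = "unclassified"


@dataclass
class CountTable:
    """Non-negative specimen × feature matrix wrapping a DataFrame."""

    df: pd.DataFrame  # index = specimens, columns = features

    def __post_init__(self):
        if self.df.index.has_duplicates:
            raise FormatError("duplicate specimen ids")
        if self.df.columns.has_duplicates:
            raise FormatError("duplicate feature ids")
        if (self.df.to_numpy() < 0).any():
            raise FormatError("negative counts")

    @property
    def specimens(self) -> list[str]:
        return list(self.df.index)

    @property
    def features(self) -> list[str]:
        return list(self.df.columns)

    def write_csv(self, path: str | os.PathLike) -> None:
        tmp = f"{path}.tmp.{os.getpid()}"
        self.df.rename_axis("specimen").to_csv(tmp)
        os.replace(tmp, path)


def read_asv_counts(path: str | os.PathLike) -> CountTable:
    """Read specimen-ASV counts from wide or long CSV (auto-detected).

    Wide: header of ASV ids, first column specimen ids.  Long: columns
    ``specimen,asv,count``; absent pairs are zero; duplicate pairs error.
    """
    head = pd.read_csv(path, nrows=0)
    cols = [c.strip().lower() for c in head.columns]
    if cols == ["specimen", "asv", "count"]:
        df = pd.read_csv(path)
        df.columns = ["specimen", "asv", "count"]
        if df.duplicated(["specimen", "asv"]).any():
            bad = df[df.duplicated(["specimen", "asv"])].index[0]
            raise FormatError(f"duplicate (specimen, asv) pair at row {bad + 2}")
        _check_counts(df["count"])
        wide = (
            df.pivot(index="specimen", columns="asv", values="count")
            .fillna(0)
            .astype(np.int64)
        )
        wide.index = wide.index.astype(str)
        wide.columns = wide.columns.astype(str)
        return CountTable(wide.sort_index())
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    arr = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = ~np.isfinite(arr)
    if bad.any():
        raise FormatError(f"non-numeric count at data row {int(np.argwhere(bad)[0][0]) + 2}")
    if (arr < 0).any():
        raise FormatError(f"negative count at data row {int(np.argwhere(arr < 0)[0][0]) + 2}")
    return CountTable(pd.DataFrame(arr, index=df.index, columns=df.columns).astype(np.int64))


def _check_counts(values: pd.Series) -> None:
    arr = pd.to_numeric(values, errors="coerce")
    bad = arr.isna()
    if bad.any():
        row = int(np.argmax(bad.to_numpy()))
        raise FormatError(f"non-numeric count at data row {row + 2}")
    neg = (arr < 0).to_numpy()
    if neg.any():
        raise FormatError(f"negative count at data row {int(np.argmax(neg)) + 2}")


def phylotype_counts(
    asv_counts: CountTable, assignment: dict[str, str]
) -> CountTable:
    """Collapse ASV columns to phylotype columns; totals conserved exactly.

    ASVs absent from the assignment accumulate into ``unclassified``.
    """
    mapping = {
        asv: assignment.get(asv, UNCLASSIFIED) for asv in asv_counts.features
    }
    out = asv_counts.df.T.groupby(mapping.get).sum().T
    names = sorted(c for c in out.columns if c != UNCLASSIFIED)
    if UNCLASSIFIED in out.columns:
        names.append(UNCLASSIFIED)
    return CountTable(out[names])


def assigned_fraction(
    asv_counts: CountTable, assignment: dict[str, str]
) -> pd.Series:
    """Per-specimen fraction of reads on assigned ASVs (NaN when no reads)."""
    assigned_cols = [a for a in asv_counts.features if a in assignment]
    totals = asv_counts.df.sum(axis=1).astype(float)
    got = asv_counts.df[assigned_cols].sum(axis=1).astype(float)
    frac = got / totals
    frac[totals == 0] = np.nan
    return frac


def normalize_counts(table: CountTable, depth: float = 10_000) -> CountTable:
    """Scale each specimen to ``depth`` pseudo-counts (real-valued).

    Zero-read specimens cannot be normalized; they are dropped with a
    warning.
    """
    if depth <= 0:
        raise UsageError("depth must be positive")
    totals = table.df.sum(axis=1).astype(float)
    zero = totals == 0
    if zero.any():
        logger.warning(
            "dropping %d zero-read specimen(s): %s",
            int(zero.sum()),
            list(table.df.index[zero])[:5],
        )
    kept = table.df.loc[~zero].astype(float)
    out = kept.mul(depth / kept.sum(axis=1), axis=0)
    return CountTable(out)


def bray_curtis(table: CountTable) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between specimens, in [0, 1].

    A pair of all-zero specimens has no defined dissimilarity; such cells
    are NaN.
    """
    if len(table.specimens) < 2:
        raise UsageError("bray_curtis needs at least two specimens")
    x = table.df.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        mat = squareform(pdist(x, metric="braycurtis"))
    zero = x.sum(axis=1) == 0
    if zero.any():
        zz = np.outer(zero, zero)
        np.fill_diagonal(zz, False)
        mat[zz] = np.nan
    np.fill_diagonal(mat, 0.0)
    return pd.DataFrame(mat, index=table.specimens, columns=table.specimens)
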