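"""Reading, writing and filtering of sparse Hi-C contact matrices.

Hi-C contact maps are handled as *sparse upper-triangular* tables: one row
per interacting bin pair ``(bin1, bin2)`` with ``bin1.start <= bin2.start``
and a non-negative interaction frequency (IF).  Two text dialects are
supported:

``triplet3``
    Three whitespace/TAB-separated columns ``start1  start2  IF``.  The
    chromosome is not stored in the file and must be supplied by the caller.

``bedpe7``
    Seven columns ``chr1 start1 end1 chr2 start2 end2 IF``.  Only
    intra-chromosomal (cis) records are accepted; trans contacts are out of
    scope.

Coordinates are 0-based half-open everywhere and must be multiples of the
bin resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ContactTable",
    "RegionSet",
    "ContactParseError",
    "read_sparse_contacts",
    "scan_sparse_contacts",
    "write_sparse_contacts",
    "read_regions_bed",
    "exclude_regions",
    "table_from_dense",
    "table_to_dense",
]

#: canonical column order of the sparse representation
_COLUMNS = ["start1", "start2", "IF"]


class ContactParseError(ValueError):
    """Raised when a contact or BED file cannot be parsed."""


@dataclass(frozen=True)
class ContactTable:
    """Sparse upper-triangular contact map for a single chromosome.

    Parameters
    ----------
    chrom : str
        Chromosome name.
    resolution : int
        Bin size in base pairs.
    df : pandas.DataFrame
        Columns ``start1``, ``start2`` (bin start coordinates, bp) and
        ``IF`` (interaction frequency).  Upper-triangular
        (``start1 <= start2``) with unique ``(start1, start2)`` keys.
    """

    chrom: str
    resolution: int
    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.df.reset_index(drop=True)[_COLUMNS].copy()
        _validate_records(df, self.resolution)
        object.__setattr__(self, "df", df)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ContactTable):
            return NotImplemented
        return (
            self.chrom == other.chrom
            and self.resolution == other.resolution
            and self._sorted().equals(other._sorted())
        )

    def _sorted(self) -> pd.DataFrame:
        return self.df.sort_values(["start1", "start2"]).reset_index(drop=True)

    @property
    def n_bins(self) -> int:
        """Number of bins spanned, from 0 to the largest occupied bin."""
        if len(self.df) == 0:
            return 0
        return int(self.df["start2"].max()) // self.resolution + 1

    def nonzero(self) -> "ContactTable":
        """Return a copy with zero-IF records removed."""
        return replace(self, df=self.df[self.df["IF"] > 0])


def _validate_records(df: pd.DataFrame, resolution: int) -> None:
    if len(df) == 0:
        return
    if (df["IF"] < 0).any():
        raise ValueError("negative interaction frequency")
    if (df["start1"] > df["start2"]).any():
        raise ValueError("records must be upper-triangular (start1 <= start2)")
    if (df["start1"] < 0).any():
        raise ValueError("negative bin coordinate")
    for col in ("start1", "start2"):
        if (df[col].to_numpy() % resolution != 0).any():
            raise ValueError(
                f"column {col}: bin start not a multiple of resolution {resolution}"
            )
    if df.duplicated(["start1", "start2"]).any():
        dup = df[df.duplicated(["start1", "start2"])].iloc[0]
        raise ValueError(
            f"duplicate bin pair ({int(dup['start1'])}, {int(dup['start2'])}); "
            "duplicate keys are an error, not summed"
        )


@dataclass(frozen=True)
class RegionSet:
    """Genomic intervals to exclude (CNV / blacklist), 0-based half-open."""

    intervals: tuple[tuple[str, int, int], ...]

    @classmethod
    def from_iterable(cls, ivs) -> "RegionSet":
        """Build a region set, merging overlapping/touching intervals per chromosome."""
        by_chrom: dict[str, list[list[int]]] = {}
        for chrom, start, end in ivs:
            if start >= end:
                raise ValueError(f"invalid interval {chrom}:{start}-{end} (start >= end)")
            by_chrom.setdefault(str(chrom), []).append([int(start), int(end)])
        merged: list[tuple[str, int, int]] = []
        for chrom in sorted(by_chrom):
            spans = sorted(by_chrom[chrom])
            cur_s, cur_e = spans[0]
            for s, e in spans[1:]:
                if s <= cur_e:
                    cur_e = max(cur_e, e)
                else:
                    merged.append((chrom, cur_s, cur_e))
                    cur_s, cur_e = s, e
            merged.append((chrom, cur_s, cur_e))
        return cls(tuple(merged))

    def __len__(self) -> int:
        return len(self.intervals)

    def for_chrom(self, chrom: str) -> list[tuple[int, int]]:
        return [(s, e) for c, s, e in self.intervals if c == chrom]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_text_table(path, n_min_cols: int):
    try:
        df = pd.read_csv(path, sep=r"\s+", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        return pd.DataFrame()
    if df.shape[1] < n_min_cols:
        raise ContactParseError(
            f"{path}: expected at least {n_min_cols} columns, found {df.shape[1]}"
        )
    return df


def read_sparse_contacts(
    path,
    format_dialect: str,
    resolution: int,
    chrom: str | None = None,
) -> ContactTable:
    """Read a sparse upper-triangular contact map from a text file.

    Records given in lower-triangular order (``start1 > start2``) are
    mirrored.  Duplicate bin pairs are a hard error.  For ``bedpe7``,
    inter-chromosomal records are rejected, and a file containing several
    (cis) chromosomes requires ``chrom`` to select one.

    Parameters
    ----------
    path : str or pathlib.Path
    format_dialect : {"triplet3", "bedpe7"}
    resolution : int
        Bin size in bp; every coordinate must be a multiple of it.
    chrom : str, optional
        Required for ``triplet3``; for ``bedpe7`` selects one chromosome
        of a multi-chromosome file.
    """
    tables = scan_sparse_contacts(path, format_dialect, resolution, chrom)
    if len(tables) != 1:
        raise ContactParseError(
            f"{path}: contains {len(tables)} chromosomes "
            f"({', '.join(sorted(tables))}); pass chrom= to select one"
        )
    return next(iter(tables.values()))


def scan_sparse_contacts(
    path,
    format_dialect: str,
    resolution: int,
    chrom: str | None = None,
) -> dict[str, ContactTable]:
    """Read a contact file, returning one :class:`ContactTable` per chromosome.

    Same contract as :func:`read_sparse_contacts` but a ``bedpe7`` file may
    hold several cis chromosomes, processed independently downstream.
    """
    if format_dialect == "triplet3":
        if chrom is None:
            raise ValueError("triplet3 dialect carries no chromosome: chrom is required")
        raw = _read_text_table(path, 3)
        if len(raw) == 0:
            return {chrom: ContactTable(chrom, resolution, _empty_df())}
        parts = {chrom: raw.iloc[:, :3].copy()}
        parts[chrom].columns = ["start1", "start2", "IF"]
    elif format_dialect == "bedpe7":
        raw = _read_text_table(path, 7)
        if len(raw) == 0:
            if chrom is not None:
                return {chrom: ContactTable(chrom, resolution, _empty_df())}
            return {}
        raw = raw.iloc[:, :7].copy()
        raw.columns = ["chr1", "start1", "end1", "chr2", "start2", "end2", "IF"]
        bad = raw.index[raw["chr1"] != raw["chr2"]]
        if len(bad):
            raise ContactParseError(
                f"{path} line {bad[0] + 1}: inter-chromosomal record "
                f"({raw.loc[bad[0], 'chr1']} vs {raw.loc[bad[0], 'chr2']}); "
                "trans contacts are out of scope"
            )
        for col_s, col_e in (("start1", "end1"), ("start2", "end2")):
            s = pd.to_numeric(raw[col_s], errors="coerce")
            e = pd.to_numeric(raw[col_e], errors="coerce")
            if ((e - s) != resolution).any():
                i = int(np.argmax((e - s).to_numpy() != resolution))
                raise ContactParseError(
                    f"{path} line {i + 1}: end - start != resolution {resolution}"
                )
        if chrom is not None:
            raw = raw[raw["chr1"] == chrom]
        parts = {
            c: g[["start1", "start2", "IF"]].copy()
            for c, g in raw.groupby("chr1", sort=True)
        }
        if chrom is not None and chrom not in parts:
            parts = {chrom: _empty_df()}
    else:
        raise ValueError(f"unknown format dialect: {format_dialect!r}")

    out: dict[str, ContactTable] = {}
    for c, df in parts.items():
        out[c] = _finalize_read(path, c, resolution, df)
    return out


def _empty_df() -> pd.DataFrame:
    return pd.DataFrame({"start1": pd.Series(dtype=int),
                         "start2": pd.Series(dtype=int),
                         "IF": pd.Series(dtype=float)})


def _finalize_read(path, chrom, resolution, df) -> ContactTable:
    if len(df) == 0:
        return ContactTable(chrom, resolution, _empty_df())
    for col in ("start1", "start2", "IF"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            i = int(vals.isna().to_numpy().argmax())
            raise ContactParseError(
                f"{path} line {df.index[i] + 1}: malformed value {df[col].iloc[i]!r} "
                f"in column {col}"
            )
        df[col] = vals
    # mirror lower-triangular records into the upper triangle
    lower = df["start1"] > df["start2"]
    if lower.any():
        s1 = df["start1"].where(~lower, df["start2"])
        s2 = df["start2"].where(~lower, df["start1"])
        df = df.assign(start1=s1, start2=s2)
    df["start1"] = df["start1"].astype(np.int64)
    df["start2"] = df["start2"].astype(np.int64)
    if (df["IF"] % 1 == 0).all():
        df["IF"] = df["IF"].astype(np.int64)
    try:
        return ContactTable(chrom, resolution, df)
    except ValueError as exc:
        raise ContactParseError(f"{path}: {exc}") from exc


def write_sparse_contacts(table: ContactTable, path, format_dialect: str) -> None:
    """Write a contact table as ``triplet3`` or ``bedpe7`` TSV (no header).

    Float IFs (post-normalization) are written with 12 significant digits so
    that a read/write round trip agrees to better than 1e-9 relative.
    """
    df = table._sorted()
    if format_dialect == "triplet3":
        out = df
    elif format_dialect == "bedpe7":
        out = pd.DataFrame(
            {
                "chr1": table.chrom,
                "start1": df["start1"],
                "end1": df["start1"] + table.resolution,
                "chr2": table.chrom,
                "start2": df["start2"],
                "end2": df["start2"] + table.resolution,
                "IF": df["IF"],
            }
        )
    else:
        raise ValueError(f"unknown format dialect: {format_dialect!r}")
    out.to_csv(path, sep="\t", header=False, index=False, float_format="%.12g")


def read_regions_bed(path) -> RegionSet:
    """Read a BED3+ file of regions to exclude; overlaps are unioned."""
    try:
        df = pd.read_csv(path, sep=r"\s+", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        return RegionSet(())
    if df.shape[1] < 3:
        raise ContactParseError(f"{path}: BED needs at least 3 columns")
    chroms = df.iloc[:, 0]
    starts = pd.to_numeric(df.iloc[:, 1], errors="coerce")
    ends = pd.to_numeric(df.iloc[:, 2], errors="coerce")
    if starts.isna().any() or ends.isna().any():
        i = int((starts.isna() | ends.isna()).to_numpy().argmax())
        raise ContactParseError(f"{path} line {i + 1}: malformed coordinate")
    if (starts >= ends).any():
        i = int((starts >= ends).to_numpy().argmax())
        raise ContactParseError(
            f"{path} line {i + 1}: start >= end "
            f"({int(starts.iloc[i])} >= {int(ends.iloc[i])})"
        )
    return RegionSet.from_iterable(zip(chroms, starts.astype(int), ends.astype(int)))


def exclude_regions(table: ContactTable, regions: RegionSet) -> ContactTable:
    """Drop every record whose bin1 *or* bin2 overlaps an excluded interval."""
    spans = regions.for_chrom(table.chrom)
    if not spans or len(table.df) == 0:
        return table
    res = table.resolution
    keep = np.ones(len(table.df), dtype=bool)
    for col in ("start1", "start2"):
        starts = table.df[col].to_numpy()
        hit = np.zeros(len(starts), dtype=bool)
        for s, e in spans:
            # bin [b, b+res) overlaps [s, e) iff b < e and b + res > s
            hit |= (starts < e) & (starts + res > s)
        keep &= ~hit
    return replace(table, df=table.df[keep])


# ---------------------------------------------------------------------------
# dense adapters (tests / compartment analysis)
# ---------------------------------------------------------------------------

def table_to_dense(table: ContactTable, n_bins: int | None = None) -> np.ndarray:
    """Densify to a symmetric ``n_bins x n_bins`` array (zeros for absent pairs)."""
    n = table.n_bins if n_bins is None else n_bins
    mat = np.zeros((n, n), dtype=float)
    i = (table.df["start1"].to_numpy() // table.resolution).astype(int)
    j = (table.df["start2"].to_numpy() // table.resolution).astype(int)
    mat[i, j] = table.df["IF"].to_numpy()
    mat[j, i] = mat[i, j]
    return mat


def table_from_dense(mat: np.ndarray, chrom: str, resolution: int) -> ContactTable:
    """Build a sparse table from the upper triangle of a symmetric array."""
    mat = np.asarray(mat)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("dense contact matrix must be square")
    i, j = np.triu_indices(mat.shape[0])
    vals = mat[i, j]
    nz = vals != 0
    out_vals = vals[nz]
    if np.all(out_vals % 1 == 0):
        out_vals = out_vals.astype(np.int64)
    df = pd.DataFrame(
        {"start1": i[nz] * resolution, "start2": j[nz] * resolution, "IF": out_vals}
    )
    return ContactTable(chrom, resolution, df)
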