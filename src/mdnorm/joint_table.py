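"""Joining two contact maps into MD-plane records.

For every bin pair present in both datasets the joint table carries

* ``D`` — distance between the interacting bins in unit lengths of the
  resolution (the off-diagonal index of the contact matrix),
* ``M = log2(IF2 / IF1)`` — the log difference between the datasets,
* ``A = (IF1 + IF2) / 2`` — the average expression of the pair.

Because a zero IF cannot be told apart from missing data, the default
``drop_any_zero`` policy keeps only pairs with both IFs positive.  Under
``keep_partial_zeros`` pairs with exactly one positive IF are carried for
bookkeeping with ``M`` undefined (NaN); they never enter trend fitting or
testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .contact_io import ContactTable

__all__ = ["JointTable", "join_pair", "md_points", "average_expression"]

ZERO_POLICIES = ("drop_any_zero", "keep_partial_zeros")

#: serialization column order; Z / p / p.adj appended after testing
_BASE_COLUMNS = ["start1", "start2", "IF1", "IF2", "D", "M", "A"]


@dataclass(frozen=True)
class JointTable:
    """Per-pair join of two contact maps with MD-plane quantities.

    ``df`` columns: ``start1, start2, IF1, IF2, D, M, A`` plus, after
    differential analysis, ``Z``, ``p``, ``p_adj`` and ``status``.
    ``M`` is NaN for records containing a zero IF (kept only under the
    ``keep_partial_zeros`` policy).
    """

    chrom: str
    resolution: int
    df: pd.DataFrame = field(repr=False)
    zero_policy: str = "drop_any_zero"
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.zero_policy not in ZERO_POLICIES:
            raise ValueError(f"unknown zero policy {self.zero_policy!r}")
        df = self.df.reset_index(drop=True)
        if df.duplicated(["start1", "start2"]).any():
            raise ValueError("duplicate (bin1, bin2) keys in joint table")
        if self.zero_policy == "drop_any_zero" and len(df):
            if (df["IF1"] <= 0).any() or (df["IF2"] <= 0).any():
                raise ValueError("zero IF present under drop_any_zero policy")
        object.__setattr__(self, "df", df)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def defined(self) -> pd.DataFrame:
        """Records with a defined M value (both IFs positive)."""
        return self.df[np.isfinite(self.df["M"])]

    def to_tsv(self, path) -> None:
        cols = _BASE_COLUMNS + [
            c for c in ("Z", "p", "p_adj", "status") if c in self.df.columns
        ]
        out = self.df[cols].copy()
        out.insert(0, "chrom", self.chrom)
        out.insert(2, "end1", out["start1"] + self.resolution)
        out.insert(5, "end2", out["start2"] + self.resolution)
        out.to_csv(path, sep="\t", index=False, float_format="%.12g")

    def side(self, which: int) -> ContactTable:
        """Extract one dataset back as a sparse :class:`ContactTable`.

        Useful after normalization to feed per-dataset analyses such as
        compartment detection.
        """
        if which not in (1, 2):
            raise ValueError("which must be 1 or 2")
        col = f"IF{which}"
        df = self.df.loc[self.df[col] > 0, ["start1", "start2", col]].rename(
            columns={col: "IF"}
        )
        return ContactTable(self.chrom, self.resolution, df)


def average_expression(IF1, IF2):
    """Average expression ``A = (IF1 + IF2) / 2`` of an interacting pair."""
    return (np.asarray(IF1, dtype=float) + np.asarray(IF2, dtype=float)) / 2.0


def join_pair(
    t1: ContactTable, t2: ContactTable, zero_policy: str = "drop_any_zero"
) -> JointTable:
    """Join two contact tables on bin-pair keys and compute D, M, A.

    Parameters
    ----------
    t1, t2 : ContactTable
        Same chromosome and resolution.
    zero_policy : {"drop_any_zero", "keep_partial_zeros"}
        ``drop_any_zero`` keeps the key intersection with both IFs > 0
        (the default, since zeros are ambiguous); ``keep_partial_zeros``
        keeps the union of keys with at least one IF > 0, flagging M as
        undefined (NaN) where either IF is zero.
    """
    if t1.chrom != t2.chrom:
        raise ValueError(f"chromosome mismatch: {t1.chrom} vs {t2.chrom}")
    if t1.resolution != t2.resolution:
        raise ValueError(
            f"resolution mismatch: {t1.resolution} vs {t2.resolution}"
        )
    if zero_policy not in ZERO_POLICIES:
        raise ValueError(f"unknown zero policy {zero_policy!r}")

    how = "inner" if zero_policy == "drop_any_zero" else "outer"
    merged = pd.merge(
        t1.df.rename(columns={"IF": "IF1"}),
        t2.df.rename(columns={"IF": "IF2"}),
        on=["start1", "start2"],
        how=how,
    )
    merged["IF1"] = merged["IF1"].fillna(0).astype(float)
    merged["IF2"] = merged["IF2"].fillna(0).astype(float)
    both = (merged["IF1"] > 0) & (merged["IF2"] > 0)
    if zero_policy == "drop_any_zero":
        merged = merged[both].reset_index(drop=True)
    else:
        either = (merged["IF1"] > 0) | (merged["IF2"] > 0)
        merged = merged[either].reset_index(drop=True)

    merged["D"] = (merged["start2"] - merged["start1"]) // t1.resolution
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.log2(merged["IF2"].to_numpy() / merged["IF1"].to_numpy())
    m[(merged["IF1"] <= 0) | (merged["IF2"] <= 0)] = np.nan
    merged["M"] = m
    merged["A"] = average_expression(merged["IF1"], merged["IF2"])
    merged = merged.sort_values(["D", "start1"]).reset_index(drop=True)
    return JointTable(t1.chrom, t1.resolution, merged[_BASE_COLUMNS], zero_policy)


def md_points(joint: JointTable) -> np.ndarray:
    """(D, M) pairs of all defined-M records, ordered by D then start1.

    Returns an ``(n, 2)`` float array — the scatter of the MD plot.
    """
    df = joint.defined.sort_values(["D", "start1"])
    return np.column_stack([df["D"].to_numpy(float), df["M"].to_numpy(float)])
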