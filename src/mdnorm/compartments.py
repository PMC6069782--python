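"""A/B compartment detection and similarity of compartment profiles.

A/B compartments are megabase-scale open/closed chromatin domains visible
in Hi-C as a checkerboard pattern.  The standard construction is used:
densify the contact map, divide each off-diagonal by its mean
(observed/expected, removing the distance decay), correlate bins
(Pearson), and take the leading eigenvector of the correlation matrix.
The sign of that first principal component labels each bin A (positive) or
B (negative); bins with empty rows are masked (NA).

Profile similarity — used to check that joint normalization preserves
compartments — is reported as the absolute Pearson correlation of the PC1
vectors, the proportion of bins with matching sign (after aligning the
arbitrary eigenvector sign), and Jaccard overlaps of the A and B label
sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contact_io import ContactTable, table_to_dense

__all__ = [
    "CompartmentProfile",
    "SimilarityReport",
    "compartment_profile",
    "compare_profiles",
]


@dataclass(frozen=True)
class CompartmentProfile:
    """Per-bin first principal component and A/B labels for one chromosome.

    ``pc1`` has unit Euclidean norm over unmasked bins and NaN at masked
    bins; ``labels`` holds "A" (pc1 > 0), "B" (pc1 < 0) or "NA".
    """

    chrom: str
    resolution: int
    starts: np.ndarray
    pc1: np.ndarray
    labels: np.ndarray

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {
                "chrom": self.chrom,
                "start": self.starts,
                "end": self.starts + self.resolution,
                "pc1": self.pc1,
                "label": self.labels,
            }
        ).to_csv(path, sep="\t", index=False, float_format="%.12g")


@dataclass(frozen=True)
class SimilarityReport:
    """The three compartment-concordance metrics (sign-alignment applied)."""

    abs_correlation: float
    sign_match_proportion: float
    jaccard_A: float
    jaccard_B: float


def compartment_profile(table: ContactTable, n_bins: int | None = None) -> CompartmentProfile:
    """Compute the compartment (PC1) profile of a contact map.

    Pipeline: densify -> observed/expected per distance -> Pearson
    correlation matrix over bins with non-zero marginals -> leading
    eigenvector.  Requires at least 10 usable bins.
    """
    mat = table_to_dense(table, n_bins=n_bins)
    n = mat.shape[0]
    mask = mat.sum(axis=0) > 0
    usable = int(mask.sum())
    if usable < 10:
        raise ValueError(f"need >= 10 non-empty bins, got {usable}")
    sub = mat[np.ix_(mask, mask)]
    m = sub.shape[0]

    # observed / expected: each off-diagonal divided by its mean
    idx = np.arange(m)
    dist = np.abs(idx[:, None] - idx[None, :])
    expected = np.array([sub[dist == d].mean() for d in range(m)])
    expected[expected == 0] = np.nan
    oe = sub / expected[dist]
    oe[~np.isfinite(oe)] = 0.0

    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(oe)
    if not np.all(np.isfinite(corr)):
        # rows with zero variance after O/E make the correlation undefined
        bad = ~np.isfinite(corr).all(axis=0)
        if bad.all():
            raise ValueError("degenerate contact map: no bin varies after O/E")
        corr[~np.isfinite(corr)] = 0.0

    evals, evecs = np.linalg.eigh(corr)
    v = evecs[:, -1]  # eigenvector of the largest eigenvalue
    v = v / np.linalg.norm(v)

    pc1 = np.full(n, np.nan)
    pc1[mask] = v
    labels = np.where(np.isnan(pc1), "NA", np.where(pc1 > 0, "A", "B"))
    starts = np.arange(n) * table.resolution
    return CompartmentProfile(table.chrom, table.resolution, starts, pc1, labels)


def compare_profiles(a: CompartmentProfile, b: CompartmentProfile) -> SimilarityReport:
    """Similarity of two compartment profiles on the same bin grid.

    The second profile's PC1 is sign-aligned to the first (an eigenvector's
    sign is arbitrary) before the sign-match and Jaccard metrics are
    computed; all four metrics are therefore invariant to global sign flips
    of either input.
    """
    if len(a.pc1) != len(b.pc1) or a.resolution != b.resolution:
        raise ValueError("profiles are on incompatible bin grids")
    both = np.isfinite(a.pc1) & np.isfinite(b.pc1)
    if both.sum() < 2:
        raise ValueError("need >= 2 jointly unmasked bins")
    x, y = a.pc1[both], b.pc1[both]
    r = float(np.corrcoef(x, y)[0, 1])
    if np.isnan(r):
        r = 0.0
    # |r| <= 1 mathematically; clamp rounding noise so identical profiles
    # score exactly 1
    if abs(r) > 1 - 1e-12:
        r = float(np.sign(r))
    if r < 0:
        y = -y
    sign_match = float(np.mean(np.sign(x) == np.sign(y)))

    lab_a = np.where(x > 0, "A", "B")
    lab_b = np.where(y > 0, "A", "B")

    def jaccard(label: str) -> float:
        sa = set(np.nonzero(lab_a == label)[0])
        sb = set(np.nonzero(lab_b == label)[0])
        union = sa | sb
        return len(sa & sb) / len(union) if union else 1.0

    return SimilarityReport(abs(r), sign_match, jaccard("A"), jaccard("B"))
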