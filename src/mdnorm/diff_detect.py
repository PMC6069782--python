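"""Z-score detection of differential chromatin interactions.

After joint normalization the M values are centered at zero and roughly
normal at every distance, so each pair's difference is scored as

    Z_i = (M_i - mean(M)) / sd(M)

with the mean and standard deviation computed from the chromosome's
retained M values.  Pairs with low average expression ``A`` are unreliable
(supported by few reads); they are filtered *before* the statistics are
computed, receive ``Z = 0`` and are excluded from testing.  Two-sided
normal p-values follow, and the false-discovery-rate correction is applied
within each distance stratum by default (each off-diagonal is its own
family of tests), with a per-chromosome option.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multitest import multipletests

from .joint_table import JointTable

__all__ = [
    "DiffParams",
    "DiffStats",
    "compute_zscores",
    "zscore_to_pvalue",
    "adjust_pvalues",
    "call_differences",
    "DifferentialInteractionTest",
]

_METHODS = {"BH": "BH", "bonferroni": "bonferroni", "holm": "holm", "none": None}


def _bh_stepup(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values, textbook step-up arithmetic.

    adj_(i) = min_{j >= i} p_(j) * n / j on the sorted vector, clipped at 1.
    Implemented directly so the adjusted values are exactly the step-up
    formula (library implementations differ in the last ulp).
    """
    n = len(p)
    order = np.argsort(p, kind="stable")
    candidates = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum(np.minimum.accumulate(candidates[::-1])[::-1], 1.0)
    out = np.empty(n)
    out[order] = adj
    return out


def _adjust(p: np.ndarray, method: str) -> np.ndarray:
    if method == "BH":
        return _bh_stepup(p)
    return multipletests(p, method=method)[1]
_SCOPES = ("per_distance", "per_chromosome")

#: record status values: tested / filtered (low A) / zero (undefined M)
STATUS_TESTED, STATUS_FILTERED, STATUS_ZERO = "tested", "filtered", "zero"


@dataclass(frozen=True)
class DiffParams:
    """Settings for differential interaction testing.

    A_min : minimum average expression for a pair to be tested (Z of
    filtered pairs is set to 0).  adjust_scope : FDR family definition,
    per distance stratum (default) or whole chromosome.  min_stratum_size :
    optional merging of small distance strata into the nearest larger-D
    stratum before correction; 0 disables (strict per-distance).
    """

    A_min: float = 15.0
    adjust_scope: str = "per_distance"
    adjust_method: str = "BH"
    alpha: float = 0.05
    min_stratum_size: int = 0

    def __post_init__(self) -> None:
        if self.A_min < 0:
            raise ValueError("A_min must be >= 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.adjust_scope not in _SCOPES:
            raise ValueError(f"unknown adjust scope {self.adjust_scope!r}")
        if self.adjust_method not in _METHODS:
            raise ValueError(f"unknown adjust method {self.adjust_method!r}")


@dataclass(frozen=True)
class DiffStats:
    """Location/scale of the retained M values used for Z conversion."""

    M_bar: float
    sigma_M: float
    n_retained: int
    n_filtered: int


def compute_zscores(joint: JointTable, params: DiffParams) -> tuple[JointTable, DiffStats]:
    """Standardize M values, filtering low-A pairs first.

    The mean and (sample, n-1) standard deviation come only from records
    with ``A >= A_min`` and defined M; those records get
    ``Z = (M - M_bar) / sigma_M`` and status ``tested``.  Low-A records get
    ``Z = 0`` and status ``filtered``; zero-IF bookkeeping records get
    status ``zero``.  Neither receives a p-value downstream.
    """
    df = joint.df.copy()
    m = df["M"].to_numpy(float)
    defined = np.isfinite(m)
    retained = defined & (df["A"].to_numpy(float) >= params.A_min)
    n_ret = int(retained.sum())
    if n_ret < 2:
        raise ValueError(
            f"need at least 2 records with A >= {params.A_min} to estimate "
            f"M statistics, got {n_ret}"
        )
    m_bar = float(np.mean(m[retained]))
    sigma = float(np.std(m[retained], ddof=1))
    if sigma == 0:
        raise ValueError("no variability after filtering (sigma_M = 0)")
    z = np.zeros(len(df))
    z[retained] = (m[retained] - m_bar) / sigma
    df["Z"] = z
    status = np.where(retained, STATUS_TESTED,
                      np.where(defined, STATUS_FILTERED, STATUS_ZERO))
    df["status"] = status
    stats_ = DiffStats(m_bar, sigma, n_ret, int((defined & ~retained).sum()))
    return replace(joint, df=df), stats_


def zscore_to_pvalue(Z) -> np.ndarray:
    """Two-sided standard-normal p-value ``2 * (1 - Phi(|Z|))``."""
    Z = np.asarray(Z, dtype=float)
    return 2.0 * stats.norm.sf(np.abs(Z))


def _attach_pvalues(joint: JointTable) -> JointTable:
    df = joint.df.copy()
    p = np.full(len(df), np.nan)
    tested = (df["status"] == STATUS_TESTED).to_numpy()
    p[tested] = zscore_to_pvalue(df.loc[tested, "Z"].to_numpy())
    df["p"] = p
    return replace(joint, df=df)


def _merge_small_strata(D: np.ndarray, min_size: int) -> np.ndarray:
    """Relabel distance strata so every family has >= min_size tests.

    Small strata are merged with the nearest stratum at larger D (the last
    one folds downward if nothing larger exists).
    """
    labels = D.astype(np.int64).copy()
    uniq = np.unique(labels)
    counts = {d: int((labels == d).sum()) for d in uniq}
    out_map: dict[int, int] = {}
    carry = 0
    pending: list[int] = []
    for d in uniq:
        pending.append(d)
        carry += counts[d]
        if carry >= min_size:
            for q in pending:
                out_map[q] = d
            pending, carry = [], 0
    if pending:  # tail too small: fold into the previous family
        target = max(out_map.values()) if out_map else pending[-1]
        for q in pending:
            out_map[q] = target
    return np.array([out_map[d] for d in labels])


def adjust_pvalues(joint: JointTable, params: DiffParams) -> JointTable:
    """Multiple-testing correction of the tested records.

    ``per_distance`` applies the correction independently within each
    distance stratum (untested records never enter a family);
    ``per_chromosome`` uses a single family.
    """
    if "p" not in joint.df.columns:
        joint = _attach_pvalues(joint)
    df = joint.df.copy()
    tested = (df["status"] == STATUS_TESTED).to_numpy()
    padj = np.full(len(df), np.nan)
    method = _METHODS[params.adjust_method]
    if method is None:
        padj[tested] = df.loc[tested, "p"].to_numpy()
    elif params.adjust_scope == "per_chromosome":
        padj[tested] = _adjust(df.loc[tested, "p"].to_numpy(), method)
    else:
        d_tested = df.loc[tested, "D"].to_numpy()
        if params.min_stratum_size > 1:
            d_tested = _merge_small_strata(d_tested, params.min_stratum_size)
        p_tested = df.loc[tested, "p"].to_numpy()
        out = np.empty_like(p_tested)
        for d in np.unique(d_tested):
            sel = d_tested == d
            out[sel] = _adjust(p_tested[sel], method)
        padj[tested] = out
    df["p_adj"] = padj
    return replace(joint, df=df)


def call_differences(joint: JointTable, params: DiffParams) -> pd.DataFrame:
    """Records called differential at ``p_adj < alpha``.

    Sorted by adjusted p ascending, then |Z| descending.
    """
    if "p_adj" not in joint.df.columns:
        raise ValueError("adjusted p-values missing: run adjust_pvalues first")
    df = joint.df
    hits = df[(df["status"] == STATUS_TESTED) & (df["p_adj"] < params.alpha)].copy()
    hits["absZ"] = hits["Z"].abs()
    hits = hits.sort_values(["p_adj", "absZ"], ascending=[True, False])
    return hits.drop(columns="absZ").reset_index(drop=True)


class DifferentialInteractionTest(BaseEstimator):
    """Z-score test for differential interactions between two Hi-C maps.

    scikit-learn-style estimator over a normalized :class:`JointTable`.
    ``fit`` standardizes M (after low-A filtering), attaches two-sided
    normal p-values and stratified FDR-adjusted p-values; ``predict``
    returns the called differences at ``alpha``.

    Parameters mirror :class:`DiffParams`.

    Attributes
    ----------
    stats_ : DiffStats
        Mean/sd of retained M values and filtering counts.
    results_ : JointTable
        Input annotated with Z, p, p_adj and status.
    """

    def __init__(self, a_min=15.0, alpha=0.05, adjust_scope="per_distance",
                 adjust_method="BH", min_stratum_size=0):
        self.a_min = a_min
        self.alpha = alpha
        self.adjust_scope = adjust_scope
        self.adjust_method = adjust_method
        self.min_stratum_size = min_stratum_size

    def _params(self) -> DiffParams:
        return DiffParams(
            A_min=self.a_min,
            adjust_scope=self.adjust_scope,
            adjust_method=self.adjust_method,
            alpha=self.alpha,
            min_stratum_size=self.min_stratum_size,
        )

    def fit(self, X: JointTable, y=None):
        if not isinstance(X, JointTable):
            raise TypeError("X must be a JointTable")
        params = self._params()
        annotated, self.stats_ = compute_zscores(X, params)
        annotated = _attach_pvalues(annotated)
        self.results_ = adjust_pvalues(annotated, params)
        return self

    def predict(self, X=None) -> pd.DataFrame:
        """Called differences (``p_adj < alpha``) of the fitted table."""
        check_is_fitted(self, "results_")
        return call_differences(self.results_, self._params())
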