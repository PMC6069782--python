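"""Loess estimation of the between-dataset bias trend and joint normalization.

The between-dataset bias of a pair of Hi-C maps shows up on the MD plot as
a distance-dependent trend in ``M``.  A locally weighted polynomial
regression (loess) of M on D estimates this trend ``f(D)``; the symmetric
rescaling

    log2(IF1') = log2(IF1) + f(D) / 2
    log2(IF2') = log2(IF2) - f(D) / 2

then centers M at zero at every distance while conserving, per pair, the
sum ``log2 IF1 + log2 IF2`` (equivalently the geometric mean of the pair).
Normalized IFs below one are dropped from further analysis.

The local regression follows the classic Cleveland construction: at a query
distance ``d`` the ``ceil(span * n)`` nearest points by ``|D - d|`` are fit
with a degree-1 (or 2) polynomial under tricube weights
``w = (1 - (|D - d| / h)^3)^3`` with bandwidth ``h`` the largest neighbor
distance.  Because D is integer-valued and many records share each
distance, the weighted least squares collapses onto per-distance count and
sum statistics, making the fit O(unique distances) per query point.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .joint_table import JointTable

__all__ = [
    "TrendFit",
    "fit_trend",
    "select_span",
    "apply_joint_normalization",
    "LoessJointNormalizer",
]


@dataclass(frozen=True)
class TrendFit:
    """Per-distance loess estimate of the log2 between-dataset bias f(D)."""

    distances: np.ndarray  # sorted unique D values seen during fitting
    fitted: np.ndarray     # f(D) per distance, log2 scale
    span: float
    degree: int
    n_points: int

    def predict(self, D) -> np.ndarray:
        """Look up f at distances observed during fitting (exact match)."""
        D = np.asarray(D)
        idx = np.searchsorted(self.distances, D)
        bad = (idx >= len(self.distances)) | (
            self.distances[np.clip(idx, 0, len(self.distances) - 1)] != D
        )
        if np.any(bad):
            missing = np.unique(np.asarray(D)[bad])[:5]
            raise ValueError(
                f"no fitted value for distance(s) {missing.tolist()}; "
                "the trend is defined only at distances present in the data"
            )
        return self.fitted[idx]

    def to_tsv(self, path) -> None:
        pd.DataFrame({"D": self.distances, "f": self.fitted}).to_csv(
            path, sep="\t", index=False, float_format="%.12g"
        )


def _group_points(x: np.ndarray, y: np.ndarray):
    """Collapse (x, y) points onto unique x with counts and y-sums."""
    ux, inv, counts = np.unique(x, return_inverse=True, return_counts=True)
    ysum = np.bincount(inv, weights=y, minlength=len(ux))
    return ux, counts.astype(float), ysum


def loess_curve(
    x: np.ndarray,
    y: np.ndarray,
    queries: np.ndarray,
    span: float,
    degree: int,
) -> np.ndarray:
    """Evaluate a tricube-weighted local polynomial fit at ``queries``.

    ``x`` may contain heavy ties (here: integer distances); all points enter
    the neighbor count individually.  The bandwidth at each query is the
    distance of the ``ceil(span * n)``-th nearest point; ties at the
    boundary receive zero weight, so their inclusion is immaterial.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    queries = np.asarray(queries, dtype=float)
    n = len(x)
    if not 0 < span <= 1:
        raise ValueError(f"span must be in (0, 1], got {span}")
    if degree not in (1, 2):
        raise ValueError(f"degree must be 1 or 2, got {degree}")
    k = int(np.ceil(span * n))
    if k < degree + 1:
        raise ValueError(
            f"span {span} selects only {k} of {n} points; "
            f"need at least degree + 1 = {degree + 1}"
        )
    ux, counts, ysum = _group_points(x, y)
    if len(ux) == 1:
        raise ValueError(
            "all predictor values identical: bandwidth undefined beyond the local mean"
        )

    out = np.empty(len(queries), dtype=float)
    for qi, d in enumerate(queries):
        dist = np.abs(ux - d)
        order = np.argsort(dist, kind="stable")
        cum = np.cumsum(counts[order])
        h = dist[order[int(np.searchsorted(cum, k))]] if cum[-1] >= k else dist[order[-1]]
        if h == 0:
            # all k nearest points sit exactly at d: local mean
            at = dist == 0
            out[qi] = ysum[at].sum() / counts[at].sum()
            continue
        sel = dist <= h
        w = (1.0 - (dist[sel] / h) ** 3) ** 3
        if w.sum() <= 0:
            # every selected point lies exactly at the bandwidth edge
            nearest = dist[sel] == dist[sel].min()
            out[qi] = ysum[sel][nearest].sum() / counts[sel][nearest].sum()
            continue
        out[qi] = _wls_at(ux[sel] - d, counts[sel], ysum[sel], w, degree)
    return out


def _wls_at(xc, counts, ysum, w, degree):
    """Weighted polynomial fit from grouped moments; returns value at xc=0."""
    wn = w * counts
    S = [np.sum(wn * xc**j) for j in range(2 * degree + 1)]
    T = [np.sum(w * xc**j * ysum) for j in range(degree + 1)]
    A = np.array([[S[j + m] for m in range(degree + 1)] for j in range(degree + 1)])
    b = np.array(T)
    try:
        beta = np.linalg.solve(A, b)
        if not np.all(np.isfinite(beta)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        return T[0] / S[0]  # degenerate design: weighted mean
    return beta[0]


def fit_trend(joint: JointTable, span: float = 0.75, degree: int = 1) -> TrendFit:
    """Fit the loess bias trend f(D) on the MD plot of a joint table.

    Only records with defined M enter the fit; f is evaluated at every
    observed distance (no interpolation is ever needed downstream since D
    is integer-valued).
    """
    df = joint.defined
    if len(df) < degree + 2:
        raise ValueError(
            f"need at least degree + 2 = {degree + 2} records with defined M, "
            f"got {len(df)}"
        )
    x = df["D"].to_numpy(float)
    y = df["M"].to_numpy(float)
    ud = np.unique(x)
    fitted = loess_curve(x, y, ud, span, degree)
    return TrendFit(ud.astype(int), fitted, span, degree, len(x))


def select_span(
    joint: JointTable,
    candidate_spans,
    k_folds: int = 5,
    seed: int = 0,
    degree: int = 1,
) -> float:
    """Pick the span minimizing k-fold cross-validated squared error.

    Deterministic given ``seed``.  A single candidate is returned unchanged.
    """
    candidates = list(candidate_spans)
    if len(candidates) == 0:
        raise ValueError("need at least one candidate span")
    if len(candidates) == 1:
        return float(candidates[0])
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    df = joint.defined
    x = df["D"].to_numpy(float)
    y = df["M"].to_numpy(float)
    n = len(x)
    if n < k_folds:
        raise ValueError(f"cannot split {n} points into {k_folds} folds")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(n)
    folds = np.array_split(idx, k_folds)
    errs = np.zeros(len(candidates))
    for fold in folds:
        mask = np.zeros(n, dtype=bool)
        mask[fold] = True
        xt, yt = x[~mask], y[~mask]
        uq = np.unique(x[mask])
        for ci, span in enumerate(candidates):
            pred_at = loess_curve(xt, yt, uq, span, degree)
            pred = pred_at[np.searchsorted(uq, x[mask])]
            errs[ci] += np.mean((y[mask] - pred) ** 2)
    return float(candidates[int(np.argmin(errs))])


def apply_joint_normalization(joint: JointTable, fit: TrendFit) -> JointTable:
    """Symmetrically rescale both IF vectors by the fitted trend.

    Per record: ``IF1' = 2^(log2 IF1 + f(D)/2)``, ``IF2' = 2^(log2 IF2 -
    f(D)/2)``; M becomes ``M - f(D)`` and A is recomputed.  Records where
    either normalized IF drops below one are removed.  Records carrying a
    zero IF (``keep_partial_zeros`` bookkeeping) pass through unchanged —
    they were never part of the fit.
    """
    df = joint.df.copy()
    defined = np.isfinite(df["M"].to_numpy())
    f = np.zeros(len(df))
    f[defined] = fit.predict(df.loc[defined, "D"].to_numpy())
    scale = np.power(2.0, f / 2.0)
    if1 = df["IF1"].to_numpy(float).copy()
    if2 = df["IF2"].to_numpy(float).copy()
    if1[defined] = if1[defined] * scale[defined]
    if2[defined] = if2[defined] / scale[defined]
    df["IF1"] = if1
    df["IF2"] = if2
    df.loc[defined, "M"] = df.loc[defined, "M"] - f[defined]
    df["A"] = (df["IF1"] + df["IF2"]) / 2.0
    # the < 1 rule: a pair is unusable if either side fell below one count
    drop = defined & ((if1 < 1) | (if2 < 1))
    df = df[~drop].reset_index(drop=True)
    return replace(joint, df=df, normalized=True)


class LoessJointNormalizer(BaseEstimator):
    """Joint loess normalizer for a pair of Hi-C datasets on the MD plot.

    A scikit-learn-style transformer operating on :class:`JointTable`
    objects.  ``fit`` estimates the per-distance log2 bias ``f(D)`` by
    locally weighted regression of M on D; ``transform`` applies the
    symmetric rescaling that centers M at zero while conserving each
    pair's geometric mean.

    Parameters
    ----------
    span : float, default 0.75
        Fraction of points in each local regression window.
    degree : int, default 1
        Local polynomial degree (1 or 2).  Degree 1 is robust in the
        sparse large-distance tail.
    span_candidates : sequence of float, optional
        When given, ``span`` is ignored and chosen by k-fold
        cross-validation over these candidates.
    cv : int, default 5
        Folds for span selection.
    random_state : int, default 0
        Seed for the CV split.

    Attributes
    ----------
    trend_ : TrendFit
        Fitted per-distance bias.
    span_ : float
        Span actually used (selected or fixed).
    n_points_ : int
        Number of (D, M) points entering the fit.
    """

    def __init__(self, span=0.75, degree=1, span_candidates=None, cv=5,
                 random_state=0):
        self.span = span
        self.degree = degree
        self.span_candidates = span_candidates
        self.cv = cv
        self.random_state = random_state

    def fit(self, X: JointTable, y=None):
        if not isinstance(X, JointTable):
            raise TypeError("X must be a JointTable")
        if self.span_candidates is not None:
            self.span_ = select_span(
                X, self.span_candidates, k_folds=self.cv,
                seed=self.random_state, degree=self.degree,
            )
        else:
            self.span_ = float(self.span)
        self.trend_ = fit_trend(X, span=self.span_, degree=self.degree)
        self.n_points_ = self.trend_.n_points
        return self

    def transform(self, X: JointTable) -> JointTable:
        check_is_fitted(self, "trend_")
        return apply_joint_normalization(X, self.trend_)

    def fit_transform(self, X: JointTable, y=None) -> JointTable:
        return self.fit(X).transform(X)
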