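"""Controlled-difference benchmark for differential interaction detection.

There is no gold standard for differential chromatin interactions, so the
benchmark manufactures one: starting from two replicate contact maps
(whose differences are assumed to be noise), a set of bin pairs is sampled,
both replicates' IFs at each sampled pair are set to their average, and one
side is multiplied by a known fold change.  Detection is then scored as a
binary classifier against this truth set, summarized by the Matthews
correlation coefficient (MCC).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .contact_io import ContactTable
from .diff_detect import DiffParams, DifferentialInteractionTest
from .joint_table import join_pair
from .loess_norm import LoessJointNormalizer

__all__ = [
    "TruthSet",
    "ConfusionCounts",
    "Metrics",
    "inject_differences",
    "evaluate_detection",
    "run_benchmark",
]


@dataclass(frozen=True)
class TruthSet:
    """Ground truth of injected differences.

    ``entries`` holds the (start1, start2) keys where a change was
    injected; ``which_side`` records, per entry, which matrix (1 or 2) was
    multiplied by ``fold_change``.
    """

    entries: tuple[tuple[int, int], ...]
    fold_change: float
    which_side: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class Metrics:
    """Classifier performance summary; MCC is 0 when undefined."""

    MCC: float
    TPR: float
    FPR: float
    precision: float


def matthews_corrcoef(c: ConfusionCounts) -> float:
    """MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).

    Defined as 0 when any factor of the denominator is 0.
    """
    tp, fp, tn, fn = (float(c.TP), float(c.FP), float(c.TN), float(c.FN))
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denom)


def inject_differences(
    t1: ContactTable,
    t2: ContactTable,
    n_changes: int,
    fold_change: float,
    seed: int,
) -> tuple[ContactTable, ContactTable, TruthSet]:
    """Inject known differences into a replicate pair.

    Eligible entries are bin pairs present with positive IF in both
    matrices.  ``n_changes`` of them are sampled uniformly without
    replacement; at each, both IFs are set to their average and one side
    (chosen uniformly at random per entry) is multiplied by
    ``fold_change``, creating a true difference of exactly
    ``|log2(fold_change)|`` on the M scale.  All other records are
    untouched.  Deterministic for a fixed seed.
    """
    if fold_change <= 0:
        raise ValueError("fold_change must be > 0")
    joined = pd.merge(
        t1.df.rename(columns={"IF": "IF1"}),
        t2.df.rename(columns={"IF": "IF2"}),
        on=["start1", "start2"],
        how="inner",
    )
    eligible = joined[(joined["IF1"] > 0) & (joined["IF2"] > 0)].reset_index(drop=True)
    if n_changes > len(eligible):
        raise ValueError(
            f"n_changes={n_changes} exceeds {len(eligible)} eligible entries"
        )
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(eligible), size=n_changes, replace=False)
    sides = rng.integers(1, 3, size=n_changes)

    chosen = eligible.iloc[pick]
    avg = (chosen["IF1"].to_numpy(float) + chosen["IF2"].to_numpy(float)) / 2.0
    new1 = np.where(sides == 1, avg * fold_change, avg)
    new2 = np.where(sides == 2, avg * fold_change, avg)

    keys = list(zip(chosen["start1"].astype(int), chosen["start2"].astype(int)))
    out1 = _set_values(t1, keys, new1)
    out2 = _set_values(t2, keys, new2)
    truth = TruthSet(tuple(keys), float(fold_change), tuple(int(s) for s in sides))
    return out1, out2, truth


def _set_values(table: ContactTable, keys, values) -> ContactTable:
    df = table.df.copy()
    df["IF"] = df["IF"].astype(float)
    idx = df.set_index(["start1", "start2"]).index
    pos = {k: i for i, k in enumerate(idx)}
    rows = [pos[k] for k in keys]
    df.iloc[rows, df.columns.get_loc("IF")] = values
    return replace(table, df=df)


def evaluate_detection(
    called: set, tested: set, truth: TruthSet
) -> tuple[ConfusionCounts, Metrics, set]:
    """Score called differences against the injected truth.

    ``called`` must be a subset of ``tested`` (the pairs that actually
    received a p-value).  Injected entries that never reached testing
    (dropped or filtered upstream) are returned separately as the third
    element rather than silently counted.
    """
    called = set(called)
    tested = set(tested)
    if not called <= tested:
        raise ValueError("called keys must be a subset of tested keys")
    truth_keys = set(truth.entries)
    truth_tested = truth_keys & tested
    lost = truth_keys - tested
    tp = len(called & truth_tested)
    fp = len(called - truth_tested)
    fn = len(truth_tested - called)
    tn = len(tested) - tp - fp - fn
    counts = ConfusionCounts(tp, fp, tn, fn)
    tpr = tp / (tp + fn) if (tp + fn) else 0.0
    fpr = fp / (fp + tn) if (fp + tn) else 0.0
    prec = tp / (tp + fp) if (tp + fp) else 0.0
    return counts, Metrics(matthews_corrcoef(counts), tpr, fpr, prec), lost


def run_benchmark(
    t1: ContactTable,
    t2: ContactTable,
    n_changes: int,
    fold_changes,
    seed: int,
    diff_params: DiffParams | None = None,
    span: float = 0.75,
    degree: int = 1,
    span_candidates=None,
) -> pd.DataFrame:
    """Full inject -> normalize -> detect -> score loop, one row per fold change.

    Each fold change gets an independent injection (child seed of ``seed``)
    into fresh copies of the input pair; the pipeline is the package
    default: drop-any-zero join, loess joint normalization, Z-score test
    with per-distance FDR.
    """
    diff_params = diff_params or DiffParams()
    fold_changes = list(fold_changes)
    child_seeds = np.random.SeedSequence(seed).generate_state(len(fold_changes))
    rows = []
    for fc, sub_seed in zip(fold_changes, child_seeds):
        p1, p2, truth = inject_differences(
            t1, t2, n_changes, fc, int(sub_seed % (2**31 - 1))
        )
        joint = join_pair(p1, p2, "drop_any_zero")
        norm = LoessJointNormalizer(
            span=span, degree=degree, span_candidates=span_candidates
        ).fit_transform(joint)
        det = DifferentialInteractionTest(
            a_min=diff_params.A_min,
            alpha=diff_params.alpha,
            adjust_scope=diff_params.adjust_scope,
            adjust_method=diff_params.adjust_method,
            min_stratum_size=diff_params.min_stratum_size,
        ).fit(norm)
        res = det.results_.df
        tested = set(
            zip(
                res.loc[res["status"] == "tested", "start1"].astype(int),
                res.loc[res["status"] == "tested", "start2"].astype(int),
            )
        )
        hits = det.predict()
        called = set(zip(hits["start1"].astype(int), hits["start2"].astype(int)))
        counts, metrics, lost = evaluate_detection(called, tested, truth)
        rows.append(
            {
                "fold_change": fc,
                "MCC": metrics.MCC,
                "TPR": metrics.TPR,
                "FPR": metrics.FPR,
                "precision": metrics.precision,
                "TP": counts.TP,
                "FP": counts.FP,
                "TN": counts.TN,
                "FN": counts.FN,
                "n_truth_untested": len(lost),
            }
        )
    return pd.DataFrame(rows)
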