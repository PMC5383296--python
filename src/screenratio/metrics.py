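"""Screening performance measures: recall, precision, MCC.

Recall R = TP/(TP+FN) counts only the classification of the actives, so
for a fixed trained model and fixed test positives it is exactly
invariant to the number of decoys in the screening library. Precision
P = TP/(TP+FP) and the Matthews correlation coefficient
MCC = (TP·TN − FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))
both degrade as the library grows at any nonzero decoy false-positive
rate. Degenerate denominators (no positive predictions, an empty class)
yield the no-skill value 0, flagged rather than raised, so trial averages
stay defined.

Counts are kept as Python integers: the MCC numerator and the product
under the root are computed in arbitrary precision before the final
square root, so the statistic is exact for any library size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a non-negative integer, got {v}")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricRecord:
    """Per-(cell, classifier, fingerprint) evaluation row."""

    ratio: float
    library_size: int
    trial: int
    classifier: str
    fingerprint: str
    counts: ConfusionCounts
    recall: float
    precision: float
    mcc: float
    degenerate: bool


def confusion(pred: Sequence[int], truth: Sequence[int]) -> ConfusionCounts:
    """Tally a hard-label confusion matrix; counts partition the test set."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {truth.shape}")
    p = pred != 0
    t = truth != 0
    return ConfusionCounts(
        tp=int(np.sum(p & t)),
        fp=int(np.sum(p & ~t)),
        tn=int(np.sum(~p & ~t)),
        fn=int(np.sum(~p & t)),
    )


def recall(cc: ConfusionCounts) -> float:
    """TP / (TP + FN); 0 when there are no positives (degenerate)."""
    denom = cc.tp + cc.fn
    if denom == 0:
        return 0.0
    return cc.tp / denom


def precision(cc: ConfusionCounts) -> float:
    """TP / (TP + FP); 0 when nothing was predicted positive (degenerate)."""
    denom = cc.tp + cc.fp
    if denom == 0:
        return 0.0
    return cc.tp / denom


def mcc(cc: ConfusionCounts) -> float:
    """Matthews correlation coefficient, exact in integer arithmetic.

    Any zero factor in the denominator gives 0 by convention.
    """
    tp, fp, tn, fn = int(cc.tp), int(cc.fp), int(cc.tn), int(cc.fn)
    denom2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom2 == 0:
        return 0.0
    # numerator and radicand in exact integer arithmetic; only the final
    # sqrt and division are floating-point
    num = tp * tn - fp * fn
    return num / math.sqrt(denom2)


def is_degenerate(cc: ConfusionCounts) -> bool:
    """True when precision or MCC fell back to the 0 convention."""
    if cc.tp + cc.fp == 0 or cc.tp + cc.fn == 0:
        return True
    return (cc.tp + cc.fp) * (cc.tp + cc.fn) * (cc.tn + cc.fp) * (cc.tn + cc.fn) == 0


def evaluate(
    pred: Sequence[int],
    truth: Sequence[int],
    ratio: float,
    library_size: int,
    trial: int,
    classifier: str,
    fingerprint: str,
) -> MetricRecord:
    """Confusion counts plus all three measures for one trial."""
    cc = confusion(pred, truth)
    return MetricRecord(
        ratio=float(ratio),
        library_size=int(library_size),
        trial=int(trial),
        classifier=classifier,
        fingerprint=fingerprint,
        counts=cc,
        recall=recall(cc),
        precision=precision(cc),
        mcc=mcc(cc),
        degenerate=is_degenerate(cc),
    )


def records_to_frame(records: Iterable[MetricRecord]) -> pd.DataFrame:
    """Flatten metric records into the canonical results table."""
    rows = []
    for r in records:
        rows.append(
            {
                "classifier": r.classifier,
                "fingerprint": r.fingerprint,
                "ratio": r.ratio,
                "library_size": r.library_size,
                "trial": r.trial,
                "tp": r.counts.tp,
                "fp": r.counts.fp,
                "tn": r.counts.tn,
                "fn": r.counts.fn,
                "recall": r.recall,
                "precision": r.precision,
                "mcc": r.mcc,
                "degenerate": r.degenerate,
            }
        )
    return pd.DataFrame(rows)


_CELL_KEYS = ["classifier", "fingerprint", "ratio", "library_size"]


def aggregate_trials(results: pd.DataFrame) -> pd.DataFrame:
    """Per-cell trial means (mean of per-trial metrics, not pooled counts).

    Every (classifier, fingerprint, ratio, library_size) cell must carry
    the same number of trials; the mean, standard deviation and trial
    count of each measure are retained.
    """
    counts = results.groupby(_CELL_KEYS)["trial"].count()
    if counts.nunique() > 1:
        bad = counts[counts != counts.max()]
        raise ValueError(f"incomplete cells (missing trials): {list(bad.index)}")
    agg = results.groupby(_CELL_KEYS, as_index=False).agg(
        recall=("recall", "mean"),
        precision=("precision", "mean"),
        mcc=("mcc", "mean"),
        recall_sd=("recall", "std"),
        precision_sd=("precision", "std"),
        mcc_sd=("mcc", "std"),
        n_trials=("trial", "count"),
        n_degenerate=("degenerate", "sum"),
    )
    return agg


def pr_quadrant(recall_val: float, precision_val: float) -> str:
    """Quadrant label of a PR point; boundaries at 0.5 (quadrant I: both >= 0.5).

    I: high recall, high precision. II: high recall, low precision.
    III: low recall, high precision. IV: low recall, low precision.
    """
    hi_r = recall_val >= 0.5
    hi_p = precision_val >= 0.5
    if hi_r and hi_p:
        return "I"
    if hi_r:
        return "II"
    if hi_p:
        return "III"
    return "IV"


def pr_trajectory(cell_means: pd.DataFrame) -> pd.DataFrame:
    """(recall, precision) points traced as the training ratio grows.

    Expects cell means for a single (classifier, fingerprint,
    library_size); returns points ordered by increasing ratio with the
    quadrant label of each point.
    """
    for key in ("classifier", "fingerprint", "library_size"):
        if cell_means[key].nunique() > 1:
            raise ValueError(f"pr_trajectory expects a single {key}")
    if cell_means["ratio"].nunique() < 2:
        raise ValueError("pr_trajectory needs at least 2 ratios")
    traj = cell_means.sort_values("ratio")[
        ["ratio", "recall", "precision"]
    ].reset_index(drop=True)
    traj["quadrant"] = [
        pr_quadrant(r, p) for r, p in zip(traj["recall"], traj["precision"])
    ]
    return traj
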