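"""Cost-effectiveness choice of the inactive:active training ratio.

Growing the negative training set improves screening performance only up
to a point, while training cost keeps rising. The cost-effectiveness
procedure quantifies, for each grid ratio, the MCC sacrificed relative to
the best ratio (delta = best_mcc - mean_mcc) and recommends the smallest
ratio whose delta does not exceed a tolerated threshold (default 0.03).
Larger thresholds can only shrink the recommended ratio, so the
threshold profile is monotone non-increasing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

#: Default tolerated MCC drop from the best ratio.
DEFAULT_THRESHOLD = 0.03


@dataclass(frozen=True)
class CostEffectivenessCurve:
    """Per-ratio mean MCC and its distance to the best ratio's MCC."""

    context: tuple  # (classifier, fingerprint, library_size)
    ratios: tuple
    mean_mcc: tuple
    deltas: tuple

    @property
    def best_mcc(self) -> float:
        return max(self.mean_mcc)


@dataclass(frozen=True)
class RatioRecommendation:
    context: tuple
    threshold: float
    optimal_ratio: float
    best_mcc: float
    mcc_at_optimal: float


def cost_effectiveness(
    mcc_by_ratio: Mapping[float, float], context: tuple = ()
) -> CostEffectivenessCurve:
    """Build the delta curve: delta(r) = best_mcc - mean_mcc(r).

    ``mcc_by_ratio`` maps each grid ratio to its trial-mean MCC. Entries
    that are NaN (all-degenerate cells) are rejected; at least one ratio
    must remain.
    """
    if not mcc_by_ratio:
        raise ValueError("no ratios supplied")
    items = sorted(mcc_by_ratio.items())
    ratios = tuple(float(r) for r, _ in items)
    mccs = tuple(float(m) for _, m in items)
    if any(m != m for m in mccs):  # NaN check
        raise ValueError("degenerate (NaN) MCC values in the curve")
    best = max(mccs)
    deltas = tuple(best - m for m in mccs)
    return CostEffectivenessCurve(
        context=tuple(context), ratios=ratios, mean_mcc=mccs, deltas=deltas
    )


def minimize_ratio(
    curve: CostEffectivenessCurve, threshold: float = DEFAULT_THRESHOLD
) -> RatioRecommendation:
    """Smallest grid ratio whose MCC is within ``threshold`` of the best.

    At threshold 0 this returns the argmax ratio (ties resolved toward
    the smaller, cheaper ratio).
    """
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    for r, m, d in zip(curve.ratios, curve.mean_mcc, curve.deltas):
        if d <= threshold:
            return RatioRecommendation(
                context=curve.context,
                threshold=float(threshold),
                optimal_ratio=r,
                best_mcc=curve.best_mcc,
                mcc_at_optimal=m,
            )
    raise AssertionError("unreachable: delta is 0 at the argmax ratio")


def threshold_profile(
    curve: CostEffectivenessCurve, thresholds: Sequence[float]
) -> dict[float, float]:
    """Recommended ratio at each threshold; monotone non-increasing."""
    return {
        float(t): minimize_ratio(curve, t).optimal_ratio for t in thresholds
    }


def recommend_all(
    cell_means: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD
) -> pd.DataFrame:
    """Recommendations for every (classifier, fingerprint, library_size).

    Input is the aggregated results table; output has one row per context
    with the recommended ratio, the best MCC over the grid and the MCC at
    the recommendation.
    """
    rows = []
    keys = ["classifier", "fingerprint", "library_size"]
    for ctx, grp in cell_means.groupby(keys):
        curve = cost_effectiveness(
            dict(zip(grp["ratio"], grp["mcc"])), context=ctx
        )
        rec = minimize_ratio(curve, threshold)
        rows.append(
            {
                "classifier": ctx[0],
                "fingerprint": ctx[1],
                "library_size": ctx[2],
                "threshold": rec.threshold,
                "optimal_ratio": rec.optimal_ratio,
                "best_mcc": rec.best_mcc,
                "mcc_at_optimal": rec.mcc_at_optimal,
            }
        )
    return pd.DataFrame(rows)
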