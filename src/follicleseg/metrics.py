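"""Pixel-based segmentation evaluation.

Predicted and ground-truth masks are compared pixel by pixel; from the
confusion counts (TP, TN, FP, FN) four metrics are derived:

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    dice        = 2 TP / (2 TP + FP + FN)
    jaccard     = TP / (TP + FP + FN)      ( = dice / (2 - dice) )
    sensitivity = TP / (TP + FN)

Undefined metrics (zero denominator) raise rather than silently returning
0, because silent zeros corrupt averages over an image set.  Aggregation
reports the arithmetic mean and the sample (n-1) standard deviation, with
4-decimal rounding applied only at serialization.  Two segmentation methods
run over the same images are compared with a paired two-sided test.
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "METRIC_NAMES",
    "UndefinedMetricError",
    "ConfusionCounts",
    "MetricReport",
    "PairedComparison",
    "confusion",
    "accuracy",
    "dice",
    "jaccard",
    "sensitivity",
    "jaccard_from_dice",
    "summarize",
    "compare_paired",
]

METRIC_NAMES = ("accuracy", "dice", "jaccard", "sensitivity")

#: Conventional significance threshold reported alongside paired p-values.
ALPHA = 0.05


class UndefinedMetricError(ZeroDivisionError):
    def __init__(self, metric: str):
        super().__init__(f"{metric} is undefined (zero denominator)")
        self.metric = metric


class ConfusionCounts(NamedTuple):
    tp: int
    tn: int
    fp: int
    fn: int


def confusion(pred: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    """Per-pixel confusion counts of a predicted mask against ground truth."""
    pred = np.asarray(pred, dtype=bool)
    gt = np.asarray(gt, dtype=bool)
    if pred.shape != gt.shape:
        raise ValueError(f"confusion: shape mismatch {pred.shape} vs {gt.shape}")
    tp = int(np.count_nonzero(pred & gt))
    fp = int(np.count_nonzero(pred & ~gt))
    fn = int(np.count_nonzero(~pred & gt))
    tn = pred.size - tp - fp - fn
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def accuracy(c: ConfusionCounts) -> float:
    den = c.tp + c.tn + c.fp + c.fn
    if den == 0:
        raise UndefinedMetricError("accuracy")
    return (c.tp + c.tn) / den


def dice(c: ConfusionCounts) -> float:
    den = 2 * c.tp + c.fp + c.fn
    if den == 0:
        raise UndefinedMetricError("dice")
    return 2 * c.tp / den


def jaccard(c: ConfusionCounts) -> float:
    den = c.tp + c.fp + c.fn
    if den == 0:
        raise UndefinedMetricError("jaccard")
    return c.tp / den


def sensitivity(c: ConfusionCounts) -> float:
    den = c.tp + c.fn
    if den == 0:
        raise UndefinedMetricError("sensitivity")
    return c.tp / den


def jaccard_from_dice(d: float) -> float:
    """Jaccard index from a Dice score via the identity J = D / (2 - D)."""
    if not 0.0 < d <= 1.0:
        raise ValueError(f"jaccard_from_dice: dice must be in (0, 1], got {d}")
    return d / (2.0 - d)


@dataclass(frozen=True)
class MetricReport:
    """Evaluation of one predicted mask against its ground truth."""

    image_id: str
    counts: ConfusionCounts
    accuracy: float
    dice: float
    jaccard: float
    sensitivity: float

    @classmethod
    def from_masks(cls, image_id: str, pred: np.ndarray, gt: np.ndarray) -> "MetricReport":
        c = confusion(pred, gt)
        return cls(
            image_id=image_id,
            counts=c,
            accuracy=accuracy(c),
            dice=dice(c),
            jaccard=jaccard(c),
            sensitivity=sensitivity(c),
        )


def _frame(reports: Mapping[str, Sequence[MetricReport]]) -> pd.DataFrame:
    methods = list(reports)
    n_rows = {m: len(v) for m, v in reports.items()}
    if len(set(n_rows.values())) != 1:
        raise ValueError(f"summarize: methods have unequal image counts {n_rows}")
    first = reports[methods[0]]
    data: dict[str, list] = {"image": [r.image_id for r in first]}
    for metric in METRIC_NAMES:
        for m in methods:
            ids = [r.image_id for r in reports[m]]
            if ids != data["image"]:
                raise ValueError("summarize: methods are not paired by image id")
            col = metric if len(methods) == 1 else f"{metric}_{m}"
            data[col] = [getattr(r, metric) for r in reports[m]]
    return pd.DataFrame(data)


def summarize(
    reports: Mapping[str, Sequence[MetricReport]] | Sequence[MetricReport],
) -> pd.DataFrame:
    """Per-image metric table with appended ``mean`` and ``sd`` rows.

    Accepts one method (a sequence of reports) or several (a mapping of
    method name to aligned report sequences, Table-style layout).  The sd
    row uses the sample (n-1) convention; a single report yields sd = 0.
    """
    if not isinstance(reports, Mapping):
        reports = {"_single_": list(reports)}
        single = True
    else:
        single = False
    if any(len(v) == 0 for v in reports.values()) or not reports:
        raise ValueError("summarize: empty report list")
    df = _frame(reports if not single else {"_single_": reports["_single_"]})
    value_cols = [c for c in df.columns if c != "image"]
    means = df[value_cols].mean()
    n = len(df)
    sds = df[value_cols].std(ddof=1) if n > 1 else means * 0.0
    tail = pd.DataFrame(
        {"image": ["mean", "sd"], **{c: [means[c], sds[c]] for c in value_cols}}
    )
    return pd.concat([df, tail], ignore_index=True)


@dataclass(frozen=True)
class PairedComparison:
    """Result of a paired two-sided location test between two methods."""

    p_value: float
    statistic: float
    test: str  # "ttest", "wilcoxon", or "degenerate"
    significant: bool
    alpha: float = ALPHA
    degenerate: bool = False


def compare_paired(a: Sequence[float], b: Sequence[float], method: str = "ttest") -> PairedComparison:
    """Two-sided paired comparison of a metric across the same images.

    The default is the paired t-test on the per-image differences; an exact
    Wilcoxon signed-rank test is available with ``method='wilcoxon'`` and is
    also the automatic fallback when the differences have zero variance but
    are not all zero.  All-zero differences return p = 1 with a degeneracy
    flag.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("compare_paired: inputs must be 1-D and equal length")
    if len(a) < 3:
        raise ValueError("compare_paired: need at least 3 paired values")
    if method not in ("ttest", "wilcoxon"):
        raise ValueError(f"compare_paired: unknown method {method!r}")
    d = a - b
    if np.all(d == 0):
        return PairedComparison(1.0, 0.0, "degenerate", False, degenerate=True)
    if method == "ttest" and np.ptp(d) <= 1e-12 * max(1.0, float(np.abs(d).max())):
        # constant non-zero differences: t statistic undefined, use ranks
        method = "wilcoxon"
    if method == "wilcoxon":
        res = stats.wilcoxon(a, b, alternative="two-sided")
        test = "wilcoxon"
    else:
        res = stats.ttest_rel(a, b, alternative="two-sided")
        test = "ttest"
    p = float(res.pvalue)
    return PairedComparison(p, float(res.statistic), test, p < ALPHA)
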