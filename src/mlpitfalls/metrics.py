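"""Classification and segmentation performance indicators.

Implements the confusion-matrix metrics (accuracy, precision, recall, F1),
the always-majority accuracy baseline for imbalanced data, the Dice and IoU
overlap scores with their exact algebraic relation

    Dice = 2·IoU / (1 + IoU),

and a two-sided Wilcoxon rank-sum (Mann-Whitney) test using the normal
approximation with tie and continuity corrections.  The rank-sum test is
implemented here rather than delegated so its small-sample behaviour can be
validated against an exact permutation enumeration.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

from .errors import DegenerateDataError

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion",
    "classification_report",
    "majority_accuracy",
    "dice",
    "iou",
    "dice_from_iou",
    "wilcoxon_rank_sum",
    "summarize_scores",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricReport:
    """Fractions in [0, 1]; a zero-denominator metric is NaN with a flag set.

    In numeric aggregation an undefined metric is treated as 0 (with a
    warning), the conservative convention for a classifier that never
    predicts — or never sees — the positive class.
    """

    accuracy: float
    precision: float
    recall: float
    f1: float
    undefined: tuple[str, ...] = ()

    def value(self, name: str) -> float:
        """Metric as a plain number: undefined metrics count as 0."""
        v = getattr(self, name)
        if name in self.undefined:
            warnings.warn(
                f"{name} undefined (zero denominator); treated as 0", stacklevel=2
            )
            return 0.0
        return float(v)


def confusion(y_true, y_pred) -> ConfusionCounts:
    yt = np.asarray(y_true).astype(int)
    yp = np.asarray(y_pred).astype(int)
    if yt.shape != yp.shape or yt.ndim != 1 or yt.size == 0:
        raise ValueError("y_true and y_pred must be equal-length nonempty vectors")
    return ConfusionCounts(
        tp=int(((yt == 1) & (yp == 1)).sum()),
        fp=int(((yt == 0) & (yp == 1)).sum()),
        fn=int(((yt == 1) & (yp == 0)).sum()),
        tn=int(((yt == 0) & (yp == 0)).sum()),
    )


def classification_report(counts: ConfusionCounts) -> MetricReport:
    if counts.total <= 0:
        raise ValueError("no samples to evaluate")
    undefined = []
    accuracy = (counts.tp + counts.tn) / counts.total

    def _ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return float("nan")
        return num / den

    precision = _ratio(counts.tp, counts.tp + counts.fp, "precision")
    recall = _ratio(counts.tp, counts.tp + counts.fn, "recall")
    if "precision" in undefined or "recall" in undefined or precision + recall == 0:
        if counts.tp + counts.fp + counts.fn == 0:
            undefined.append("f1")
            f1 = float("nan")
        else:
            f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return MetricReport(
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f1=f1,
        undefined=tuple(undefined),
    )


def majority_accuracy(labels) -> float:
    """Accuracy of the trivial predictor that always outputs the majority class."""
    y = np.asarray(labels).astype(int)
    if y.size == 0:
        raise ValueError("labels must be nonempty")
    pos = (y == 1).mean()
    return float(max(pos, 1.0 - pos))


def _mask_pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    xa, ya = np.asarray(x).astype(bool), np.asarray(y).astype(bool)
    if xa.shape != ya.shape:
        raise ValueError(f"mask shapes differ: {xa.shape} vs {ya.shape}")
    return xa, ya


def dice(x, y) -> float:
    """Dice score 2|X∩Y|/(|X|+|Y|); two empty masks count as perfect overlap."""
    xa, ya = _mask_pair(x, y)
    denom = int(xa.sum()) + int(ya.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((xa & ya).sum()) / denom


def iou(x, y) -> float:
    """Jaccard index |X∩Y|/|X∪Y|; two empty masks count as perfect overlap."""
    xa, ya = _mask_pair(x, y)
    union = int((xa | ya).sum())
    if union == 0:
        return 1.0
    return int((xa & ya).sum()) / union


def dice_from_iou(j: float) -> float:
    """The exact identity Dice = 2j/(1+j) mapping IoU to Dice."""
    if not 0.0 <= j <= 1.0:
        raise ValueError("IoU must lie in [0, 1]")
    return 2.0 * j / (1.0 + j)


_EXACT_ENUMERATION_LIMIT = 500  # max C(n, n1) for the exact small-sample path


def wilcoxon_rank_sum(a, b) -> tuple[float, float]:
    """Two-sided rank-sum test; returns (z, p).

    ``z`` is the standardized rank sum of the first sample with tie
    correction and a 0.5 continuity correction toward the null.  For small
    samples (at most 500 group assignments, which covers any pair with
    n1+n2 ≤ 10) the p-value is the exact two-sided permutation probability
    of a rank sum at least as extreme as observed; larger samples use the
    normal approximation.  Raises on zero rank variance (all values tied
    across both samples).
    """
    av = np.asarray(a, dtype=float).ravel()
    bv = np.asarray(b, dtype=float).ravel()
    if av.size == 0 or bv.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = av.size, bv.size
    n = n1 + n2
    combined = np.concatenate([av, bv])
    ranks = rankdata(combined)
    r1 = ranks[:n1].sum()
    mean_r1 = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / ((n * (n - 1)) if n > 1 else 1)
    var_r1 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_r1 <= 0:
        raise DegenerateDataError("rank variance is zero: all values identical")
    diff = r1 - mean_r1
    cc = min(0.5, abs(diff))  # continuity correction, shrunk toward the null
    z = float((diff - np.sign(diff) * cc) / np.sqrt(var_r1))
    if math.comb(n, n1) <= _EXACT_ENUMERATION_LIMIT:
        observed = abs(diff)
        count = total = 0
        for idx in itertools.combinations(range(n), n1):
            total += 1
            if abs(ranks[list(idx)].sum() - mean_r1) >= observed - 1e-9:
                count += 1
        return z, count / total
    p = min(1.0, 2.0 * norm.sf(abs(z)))
    return z, float(p)


def summarize_scores(values) -> dict[str, float]:
    """Min / mean / max / SD of a score vector (SD with n−1 denominator)."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("values must be nonempty")
    return {
        "min": float(v.min()),
        "mean": float(v.mean()),
        "max": float(v.max()),
        "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
    }
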