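"""Confusion-matrix metrics, macro multi-class extension, and the Wilcoxon
signed-rank comparison used to contrast paired model runs.

Binary metrics follow the standard count definitions
(accuracy ``(TP+TN)/total``, recall ``TP/(TP+FN)``, precision ``TP/(TP+FP)``,
F ``2PR/(P+R)``); sensitivity is reported as its own field but equals recall.
The 4-class task is scored by unweighted one-vs-rest macro averaging, with
overall accuracy taken from the confusion-matrix trace.  Zero-denominator
ratios evaluate to 0 and are flagged rather than raised, so batch evaluation
stays total.

The Wilcoxon test is implemented here (exact tail by enumeration over sign
patterns for n <= 20, normal approximation with continuity correction above)
so the test suite can cross-check it against an independent reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import norm, rankdata

from .exceptions import DegenerateTestError, ParameterError, SchemaError

__all__ = [
    "ConfusionMatrix",
    "MetricRecord",
    "WilcoxonResult",
    "confusion",
    "binary_metrics",
    "macro_metrics",
    "wilcoxon_signed_rank",
]


@dataclass
class ConfusionMatrix:
    """C x C counts; rows are true classes, columns predicted classes."""

    counts: np.ndarray
    class_names: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        c = len(self.class_names)
        if self.counts.shape != (c, c):
            raise SchemaError(f"counts shape {self.counts.shape} != ({c}, {c})")
        if (self.counts < 0).any():
            raise SchemaError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class MetricRecord:
    """Proportion-valued metrics; ``undefined`` flags zero-denominator fields."""

    accuracy: float
    recall: float
    precision: float
    f_measure: float
    sensitivity: float
    undefined: tuple[str, ...] = ()


@dataclass
class WilcoxonResult:
    statistic: float  # min of the signed-rank sums
    p_value: float  # two-sided
    n_effective: int  # pairs left after dropping zero differences
    method: str = "exact"


def confusion(
    true_labels: Sequence, predicted: Sequence, class_names: Sequence[str]
) -> ConfusionMatrix:
    """Tally a confusion matrix; unknown labels raise, empty input raises."""
    true_arr = np.asarray([str(v) for v in true_labels], dtype=object)
    pred_arr = np.asarray([str(v) for v in predicted], dtype=object)
    if true_arr.size == 0:
        raise ParameterError("empty label vectors")
    if true_arr.size != pred_arr.size:
        raise SchemaError(
            f"length mismatch: {true_arr.size} true vs {pred_arr.size} predicted"
        )
    index = {str(c): i for i, c in enumerate(class_names)}
    counts = np.zeros((len(index), len(index)), dtype=int)
    for t, p in zip(true_arr, pred_arr):
        if t not in index or p not in index:
            raise ParameterError(f"label outside class_names: {t!r} / {p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, [str(c) for c in class_names])


def binary_metrics(tp: int, fp: int, fn: int, tn: int) -> MetricRecord:
    """Accuracy, recall, precision, F and sensitivity from the four counts."""
    for name, v in (("tp", tp), ("fp", fp), ("fn", fn), ("tn", tn)):
        if v < 0:
            raise ParameterError(f"{name} must be >= 0, got {v}")
    total = tp + fp + fn + tn
    if total == 0:
        raise ParameterError("all counts are zero")
    flags: list[str] = []

    def ratio(num, den, name):
        if den == 0:
            flags.append(name)
            return 0.0
        return num / den

    accuracy = (tp + tn) / total
    recall = ratio(tp, tp + fn, "recall")
    precision = ratio(tp, tp + fp, "precision")
    f = ratio(2 * precision * recall, precision + recall, "f_measure")
    return MetricRecord(accuracy, recall, precision, f, recall, tuple(flags))


def macro_metrics(cm: ConfusionMatrix) -> MetricRecord:
    """Unweighted one-vs-rest macro averages; accuracy is the matrix trace rate."""
    c = len(cm.class_names)
    if c < 2:
        raise ParameterError("need at least 2 classes")
    total = cm.total
    if total == 0:
        raise ParameterError("empty confusion matrix")
    recalls, precisions, fs = [], [], []
    flags: list[str] = []
    for i in range(c):
        tp = int(cm.counts[i, i])
        fn = int(cm.counts[i].sum()) - tp
        fp = int(cm.counts[:, i].sum()) - tp
        tn = total - tp - fn - fp
        rec = binary_metrics(tp, fp, fn, tn)
        recalls.append(rec.recall)
        precisions.append(rec.precision)
        fs.append(rec.f_measure)
        flags.extend(f"{cm.class_names[i]}:{name}" for name in rec.undefined)
    macro_recall = float(np.mean(recalls))
    return MetricRecord(
        accuracy=float(np.trace(cm.counts) / total),
        recall=macro_recall,
        precision=float(np.mean(precisions)),
        f_measure=float(np.mean(fs)),
        sensitivity=macro_recall,
        undefined=tuple(flags),
    )


def _exact_tail(double_ranks: np.ndarray, double_stat: int) -> float:
    """P(W+ <= stat) under the null, by counting all sign patterns.

    Works on ranks doubled to integers so midranks stay exact; the count is a
    convolution over per-pair ``(1 + z^rank)`` polynomials, which enumerates
    the ``2^n`` sign patterns exactly.
    """
    total = int(double_ranks.sum())
    poly = np.zeros(total + 1, dtype=float)
    poly[0] = 1.0
    for r in double_ranks:
        shifted = np.zeros_like(poly)
        shifted[r:] = poly[: total + 1 - r]
        poly = poly + shifted
    return float(poly[: double_stat + 1].sum() / 2 ** len(double_ranks))


def wilcoxon_signed_rank(
    a: Sequence[float], b: Sequence[float], method: str = "auto"
) -> WilcoxonResult:
    """Two-sided paired signed-rank test on ``a - b``.

    Zero differences are dropped; ties get midranks.  ``method`` is ``"exact"``
    (enumeration), ``"approx"`` (normal with continuity and tie correction) or
    ``"auto"`` (exact up to n=20).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise SchemaError("paired vectors must have equal length")
    d = a - b
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise DegenerateTestError("all paired differences are zero")
    if n < 5:
        raise ParameterError(f"need >= 5 non-zero differences, got {n}")
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    stat = min(w_plus, w_minus)
    if method == "auto":
        method = "exact" if n <= 20 else "approx"
    if method == "exact":
        double_ranks = np.rint(2 * ranks).astype(int)
        p = min(1.0, 2.0 * _exact_tail(double_ranks, int(round(2 * stat))))
    elif method == "approx":
        mu = n * (n + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - ((tie_counts**3 - tie_counts).sum()) / 48.0
        z = (stat - mu + 0.5) / np.sqrt(var)
        p = min(1.0, 2.0 * float(norm.cdf(z)))
    else:
        raise ParameterError(f"unknown method {method!r}")
    return WilcoxonResult(stat, p, n, method)
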