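"""Binary confusion matrix and the six-metric evaluation report.

The disease class ("bipolar") is the positive class by convention.  All six
metrics — accuracy, sensitivity, specificity, precision, F1 and the
geometric mean sqrt(sensitivity * specificity) — are reported as
percentages.  A ratio with a zero denominator is flagged as undefined
(NaN value plus an explanation) rather than silently zeroed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

__all__ = ["ConfusionMatrix", "MetricReport", "confusion_matrix", "metric_report"]


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts with ``positive`` naming the disease-positive class."""

    tp: int
    fn: int
    fp: int
    tn: int
    positive: str = "bipolar"
    negative: str = "control"

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def as_table(self) -> str:
        """Labeled text table, predicted classes in columns."""
        p, n = self.positive, self.negative
        w = max(len(p), len(n), 6) + 2
        corner = "true \\ pred"
        head = f"{corner:>{w}} {p:>{w}} {n:>{w}}"
        r1 = f"{p:>{w}} {self.tp:>{w}} {self.fn:>{w}}"
        r2 = f"{n:>{w}} {self.fp:>{w}} {self.tn:>{w}}"
        return "\n".join([head, r1, r2])


@dataclass
class MetricReport:
    """Six metrics in percent; ``undefined`` maps metric -> reason."""

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    geometric_mean: float
    undefined: dict[str, str] = field(default_factory=dict)

    _FIELDS = ("accuracy", "sensitivity", "specificity", "precision", "f1",
               "geometric_mean")

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self._FIELDS}
        d["undefined"] = dict(self.undefined)
        return d

    def to_json(self, path=None) -> str:
        def _round(v):
            return None if isinstance(v, float) and math.isnan(v) else round(v, 2)
        payload = {k: _round(getattr(self, k)) for k in self._FIELDS}
        payload["undefined"] = dict(self.undefined)
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("metric,percent\n")
            for k in self._FIELDS:
                v = getattr(self, k)
                fh.write(f"{k},{'' if math.isnan(v) else f'{v:.2f}'}\n")


def confusion_matrix(y_true: Sequence, y_pred: Sequence,
                     positive: str = "bipolar",
                     negative: str | None = None) -> ConfusionMatrix:
    """Count tp/fn/fp/tn over paired label sequences.

    Labels may be any hashable values; exactly two distinct classes are
    expected and ``positive`` must be one of them.  An unknown label raises
    with the offending value named.
    """
    if len(y_true) != len(y_pred):
        raise ValueError(
            f"label sequences differ in length: {len(y_true)} vs {len(y_pred)}"
        )
    if len(y_true) == 0:
        raise ValueError("cannot build a confusion matrix from zero samples")
    classes = set(y_true) | set(y_pred)
    if negative is None:
        rest = classes - {positive}
        if len(rest) > 1:
            raise ValueError(f"more than two classes present: {sorted(map(str, classes))}")
        negative = rest.pop() if rest else "control"
    known = {positive, negative}
    for lab in classes:
        if lab not in known:
            raise ValueError(f"unknown label {lab!r}; expected one of {sorted(map(str, known))}")
    tp = fn = fp = tn = 0
    for t, p in zip(y_true, y_pred):
        if t == positive:
            if p == positive:
                tp += 1
            else:
                fn += 1
        else:
            if p == positive:
                fp += 1
            else:
                tn += 1
    return ConfusionMatrix(tp=tp, fn=fn, fp=fp, tn=tn,
                           positive=str(positive), negative=str(negative))


def metric_report(cm: ConfusionMatrix) -> MetricReport:
    """Compute the six metrics (percent) from a confusion matrix.

    accuracy = (tp+tn)/total, sensitivity = tp/(tp+fn),
    specificity = tn/(tn+fp), precision = tp/(tp+fp),
    f1 = 2*precision*sensitivity/(precision+sensitivity),
    geometric_mean = sqrt(sensitivity * specificity).
    """
    if cm.total == 0:
        raise ValueError("metric computation requires at least one sample")
    undefined: dict[str, str] = {}

    def ratio(num: int, den: int, name: str, reason: str) -> float:
        if den == 0:
            undefined[name] = reason
            return math.nan
        return num / den

    acc = (cm.tp + cm.tn) / cm.total
    sen = ratio(cm.tp, cm.tp + cm.fn, "sensitivity", "no positive-class samples (tp+fn=0)")
    spe = ratio(cm.tn, cm.tn + cm.fp, "specificity", "no negative-class samples (tn+fp=0)")
    pre = ratio(cm.tp, cm.tp + cm.fp, "precision", "no positive predictions (tp+fp=0)")
    if math.isnan(sen) or math.isnan(pre):
        undefined.setdefault("f1", "sensitivity or precision undefined")
        f1 = math.nan
    elif pre + sen == 0:
        undefined["f1"] = "precision + sensitivity = 0"
        f1 = math.nan
    else:
        f1 = 2 * pre * sen / (pre + sen)
    if math.isnan(sen) or math.isnan(spe):
        undefined.setdefault("geometric_mean", "sensitivity or specificity undefined")
        gm = math.nan
    else:
        gm = math.sqrt(sen * spe)
    return MetricReport(
        accuracy=100.0 * acc,
        sensitivity=100.0 * sen,
        specificity=100.0 * spe,
        precision=100.0 * pre,
        f1=100.0 * f1,
        geometric_mean=100.0 * gm,
        undefined=undefined,
    )
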