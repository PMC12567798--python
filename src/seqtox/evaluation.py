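"""Balanced binary-classification evaluation.

Ten measures computed from confusion counts (plus AUC from scores):
NPV, PPV, specificity, sensitivity, accuracy, MCC, nMCC = (1+MCC)/2,
the overall performance measure

    OPM = (NPV+PPV) * (specificity+sensitivity) * (accuracy+nMCC) / 8,

F1 and AUC.  OPM lies in [0, 1] and equals 1 only for a perfect
classifier; it penalizes predictors whose headline accuracy hides a
strong class bias.  Counts are accepted as reals so fold-averaged
confusion tables evaluate exactly like integer ones.

Conventions: any 0/0 ratio is defined as 0 (flagged in the report), as
is MCC with a zero denominator; displayed values round half-up to three
decimals.
"""

from __future__ import annotations

import dataclasses
import math
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "metrics_from_counts",
    "counts_from_predictions",
    "auc_from_scores",
    "compare_table",
    "round3",
]

_METRIC_ORDER = [
    "NPV", "PPV", "specificity", "sensitivity", "accuracy",
    "MCC", "nMCC", "OPM", "F1", "AUC",
]


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN; reals are allowed for fold-averaged tables."""

    tp: float
    tn: float
    fp: float
    fn: float

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion counts are all zero")

    @property
    def total(self) -> float:
        return self.tp + self.tn + self.fp + self.fn


@dataclasses.dataclass
class MetricsReport:
    NPV: float
    PPV: float
    specificity: float
    sensitivity: float
    accuracy: float
    MCC: float
    nMCC: float
    OPM: float
    F1: float
    AUC: float | None = None
    undefined: tuple[str, ...] = ()  # ratios that hit 0/0 and were set to 0

    def to_dict(self, round_display: bool = False) -> dict:
        out = {}
        for name in _METRIC_ORDER:
            v = getattr(self, name)
            if v is None:
                continue
            out[name] = round3(v) if round_display else v
        return out


def _ratio(num: float, den: float, name: str, undefined: list[str]) -> float:
    if den == 0:
        undefined.append(name)
        return 0.0
    return num / den


def metrics_from_counts(c: ConfusionCounts) -> MetricsReport:
    """All count-derivable measures (AUC needs scores and is left unset)."""
    undefined: list[str] = []
    npv = _ratio(c.tn, c.tn + c.fn, "NPV", undefined)
    ppv = _ratio(c.tp, c.tp + c.fp, "PPV", undefined)
    spec = _ratio(c.tn, c.tn + c.fp, "specificity", undefined)
    sens = _ratio(c.tp, c.tp + c.fn, "sensitivity", undefined)
    acc = (c.tp + c.tn) / c.total
    mcc_den = math.sqrt(
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if mcc_den == 0:
        undefined.append("MCC")
        mcc = 0.0
    else:
        mcc = (c.tp * c.tn - c.fp * c.fn) / mcc_den
    nmcc = (1 + mcc) / 2
    opm = (npv + ppv) * (spec + sens) * (acc + nmcc) / 8
    f1 = _ratio(2 * ppv * sens, ppv + sens, "F1", undefined)
    return MetricsReport(
        NPV=npv, PPV=ppv, specificity=spec, sensitivity=sens, accuracy=acc,
        MCC=mcc, nMCC=nmcc, OPM=opm, F1=f1, undefined=tuple(undefined),
    )


def counts_from_predictions(
    y_true: Sequence[int], y_pred: Sequence[int]
) -> ConfusionCounts:
    """Confusion counts from 0/1 label vectors (positive class = 1)."""
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    if yt.shape != yp.shape:
        raise ValueError("label vectors differ in length")
    return ConfusionCounts(
        tp=float(np.sum((yt == 1) & (yp == 1))),
        tn=float(np.sum((yt == 0) & (yp == 0))),
        fp=float(np.sum((yt == 0) & (yp == 1))),
        fn=float(np.sum((yt == 1) & (yp == 0))),
    )


def auc_from_scores(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve via the rank (Mann–Whitney) statistic.

    Equals the probability that a random positive outscores a random
    negative, ties counting one half.
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(s)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def round3(x: float) -> float:
    """Half-up rounding to 3 decimals, the convention of printed tables."""
    return float(Decimal(repr(x)).quantize(Decimal("0.001"), rounding=ROUND_HALF_UP))


def compare_table(
    entries: Iterable[tuple[str, ConfusionCounts] | tuple[str, ConfusionCounts, tuple]],
    n_inputs: float | None = None,
) -> pd.DataFrame:
    """Method-comparison table: one row per method, ten measures at 3 d.p.

    Each entry is ``(name, counts)`` or ``(name, counts, (scores, labels))``;
    the optional score pair adds AUC.  Coverage is the fraction of
    ``n_inputs`` the method produced predictions for (1.0 when
    ``n_inputs`` is omitted).
    """
    rows = []
    entries = list(entries)
    if not entries:
        raise ValueError("compare_table needs at least one entry")
    for entry in entries:
        name, counts = entry[0], entry[1]
        report = metrics_from_counts(counts)
        if len(entry) > 2 and entry[2] is not None:
            scores, labels = entry[2]
            report.AUC = auc_from_scores(scores, labels)
        row = {"method": name}
        row.update({k: round3(v) for k, v in report.to_dict().items()})
        row["coverage"] = round3(counts.total / n_inputs) if n_inputs else 1.0
        rows.append(row)
    return pd.DataFrame(rows).set_index("method")


def format_table(table: pd.DataFrame) -> str:
    """Aligned plain-text rendering of a comparison table."""
    return table.to_string(float_format=lambda v: f"{v:.3f}")
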