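"""Uncertain-aware evaluation of three-way pathogenicity calls.

Calls take values {benign, uncertain, pathogenic} while the ground truth is
binary {benign, pathogenic}, so the confusion table is 3x2.  Two denominator
conventions coexist and are kept as separate, explicitly named fields:

* accuracy / sensitivity / specificity / precision / MCC exclude uncertain
  calls (they grade only the variants the classifier committed on);
* the discovery rate for a class divides correct calls by the full column
  total including uncertain (it grades yield: what fraction of all truly
  benign/pathogenic variants received the right committed call).

Metrics with a zero denominator are reported as None, never as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .annotation import FiveTierLabel, ValidationError
from .model import CALL_BENIGN, CALL_PATHOGENIC, CALL_UNCERTAIN

__all__ = [
    "ConfusionTable3x2",
    "MetricsReport",
    "build_confusion",
    "metrics_from_confusion",
    "roc_auc",
    "probability_distribution_by_label",
    "round_percent",
]

_PRED_ROWS = (CALL_BENIGN, CALL_UNCERTAIN, CALL_PATHOGENIC)
_TRUE_COLS = (CALL_BENIGN, CALL_PATHOGENIC)


def round_percent(fraction: float, ndigits: int = 2) -> float:
    """Fraction -> percentage rounded half-up to ``ndigits`` decimals."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(fraction * 100.0)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionTable3x2:
    """Counts c[predicted][true] for three-way calls against binary truth."""

    benign_benign: int
    benign_pathogenic: int
    uncertain_benign: int
    uncertain_pathogenic: int
    pathogenic_benign: int
    pathogenic_pathogenic: int

    def __post_init__(self) -> None:
        if any(v < 0 for v in self._cells()):
            raise ValidationError("confusion counts must be non-negative")

    def _cells(self) -> tuple[int, ...]:
        return (
            self.benign_benign,
            self.benign_pathogenic,
            self.uncertain_benign,
            self.uncertain_pathogenic,
            self.pathogenic_benign,
            self.pathogenic_pathogenic,
        )

    @property
    def total(self) -> int:
        return sum(self._cells())

    def __add__(self, other: "ConfusionTable3x2") -> "ConfusionTable3x2":
        return ConfusionTable3x2(
            *(a + b for a, b in zip(self._cells(), other._cells()))
        )

    def as_frame(self) -> pd.DataFrame:
        data = {
            CALL_BENIGN: [
                self.benign_benign,
                self.uncertain_benign,
                self.pathogenic_benign,
            ],
            CALL_PATHOGENIC: [
                self.benign_pathogenic,
                self.uncertain_pathogenic,
                self.pathogenic_pathogenic,
            ],
        }
        return pd.DataFrame(data, index=list(_PRED_ROWS)).rename_axis(
            index="predicted", columns="true"
        )


@dataclass(frozen=True)
class MetricsReport:
    """Derived metrics; None marks a metric whose denominator was zero."""

    included_fraction: float
    uncertain_fraction: float
    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    precision_benign: float | None
    precision_pathogenic: float | None
    mcc: float | None
    discovery_benign: float | None
    discovery_pathogenic: float | None
    auc: float | None = None

    def as_dict(self) -> dict[str, float | None]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def undefined_metrics(self) -> list[str]:
        return [
            f.name
            for f in fields(self)
            if f.name != "auc" and getattr(self, f.name) is None
        ]


def build_confusion(
    calls: Sequence[str], labels: Sequence[str] | np.ndarray
) -> ConfusionTable3x2:
    """Tally three-way calls against binary truth labels.

    ``labels`` may be the strings benign/pathogenic or the integers 0/1.
    """
    if len(calls) != len(labels):
        raise ValidationError(
            f"calls ({len(calls)}) and labels ({len(labels)}) differ in length"
        )
    norm_labels = []
    for lab in labels:
        if lab in (0, 1):
            norm_labels.append(_TRUE_COLS[int(lab)])
        elif lab in _TRUE_COLS:
            norm_labels.append(lab)
        else:
            raise ValidationError(f"truth labels must be binary, got {lab!r}")
    cells = {(p, t): 0 for p in _PRED_ROWS for t in _TRUE_COLS}
    for call, truth in zip(calls, norm_labels):
        if call not in _PRED_ROWS:
            raise ValidationError(f"unknown call {call!r}")
        cells[(call, truth)] += 1
    return ConfusionTable3x2(
        benign_benign=cells[(CALL_BENIGN, CALL_BENIGN)],
        benign_pathogenic=cells[(CALL_BENIGN, CALL_PATHOGENIC)],
        uncertain_benign=cells[(CALL_UNCERTAIN, CALL_BENIGN)],
        uncertain_pathogenic=cells[(CALL_UNCERTAIN, CALL_PATHOGENIC)],
        pathogenic_benign=cells[(CALL_PATHOGENIC, CALL_BENIGN)],
        pathogenic_pathogenic=cells[(CALL_PATHOGENIC, CALL_PATHOGENIC)],
    )


def _ratio(num: float, den: float) -> float | None:
    return None if den == 0 else num / den


def metrics_from_confusion(ct: ConfusionTable3x2) -> MetricsReport:
    """Full metric suite from a 3x2 confusion table.

    With TP = pathogenic calls on pathogenic variants, TN = benign calls on
    benign variants, FP = pathogenic calls on benign variants and FN = benign
    calls on pathogenic variants (uncertain calls excluded):

        accuracy    = (TP + TN) / (TP + TN + FP + FN)
        sensitivity = TP / (TP + FN)       specificity = TN / (TN + FP)
        MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

    Discovery rates use full column totals (uncertain included); precisions
    use row totals.
    """
    tn = ct.benign_benign
    fn = ct.benign_pathogenic
    fp = ct.pathogenic_benign
    tp = ct.pathogenic_pathogenic
    n_uncertain = ct.uncertain_benign + ct.uncertain_pathogenic
    total = ct.total
    included = tp + tn + fp + fn

    mcc: float | None
    mcc_den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if mcc_den == 0:
        mcc = None
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(mcc_den)

    return MetricsReport(
        included_fraction=_ratio(included, total) if total else 0.0,
        uncertain_fraction=_ratio(n_uncertain, total) if total else 0.0,
        accuracy=_ratio(tp + tn, included),
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        precision_benign=_ratio(tn, tn + fn),
        precision_pathogenic=_ratio(tp, tp + fp),
        mcc=mcc,
        discovery_benign=_ratio(tn, tn + ct.uncertain_benign + fp),
        discovery_pathogenic=_ratio(tp, tp + ct.uncertain_pathogenic + fn),
    )


def roc_auc(
    probabilities: Sequence[float] | np.ndarray,
    labels: Sequence[int] | np.ndarray,
    included_only: bool = False,
    p_ct: float = 0.95,
) -> float | None:
    """Rank-based (Mann-Whitney) area under the ROC curve; ties share rank.

    With ``included_only`` the variants abstained on at p_ct (probability in
    the open interval (1 - p_ct, p_ct)) are removed before ranking.  Returns
    None (undefined) when only one class remains.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(p) != len(y):
        raise ValidationError("probabilities and labels differ in length")
    if included_only:
        keep = (p >= p_ct) | (p <= 1.0 - p_ct)
        p, y = p[keep], y[keep]
    if len(np.unique(y)) < 2:
        return None
    return float(roc_auc_score(y, p))


def probability_distribution_by_label(
    probabilities: Sequence[float] | np.ndarray,
    five_tier_labels: Sequence[FiveTierLabel | str],
    p_ct: float = 0.95,
) -> pd.DataFrame:
    """Per-label summary of predicted pathogenicity probabilities.

    One row per five-tier label present in the input: count, quartiles and
    the fractions called pathogenic (>= p_ct) and benign (<= 1 - p_ct).
    Useful for strip-plot style views of how intermediate labels (likely
    benign / likely pathogenic / uncertain) distribute between the two
    committed calls.
    """
    p = np.asarray(probabilities, dtype=float)
    labels = [FiveTierLabel(l) for l in five_tier_labels]
    if len(p) != len(labels):
        raise ValidationError("probabilities and labels differ in length")
    rows = []
    for label in FiveTierLabel:
        mask = np.array([l is label for l in labels], dtype=bool)
        if not mask.any():
            continue
        group = p[mask]
        q = np.quantile(group, [0.0, 0.25, 0.5, 0.75, 1.0])
        rows.append(
            {
                "label": label.value,
                "n": int(mask.sum()),
                "min": q[0],
                "q25": q[1],
                "median": q[2],
                "q75": q[3],
                "max": q[4],
                "frac_called_pathogenic": float((group >= p_ct).mean()),
                "frac_called_benign": float((group <= 1.0 - p_ct).mean()),
            }
        )
    return pd.DataFrame(rows)
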