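"""Cohort statistics: exact 2x2 comparisons and confusion summaries.

Detector-vs-detector comparisons use Fisher's exact test with the
two-sided probability-mass rule (the p-value sums the probabilities of all
margin-preserving tables no more probable than the observed one, with a
1e-7 relative gate on the comparison).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from scipy.stats import fisher_exact as _scipy_fisher

from .errors import DataError

__all__ = [
    "ContingencyTable2x2",
    "fisher_exact_two_sided",
    "ConfusionSummary",
    "confusion_summary",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts: row 1 = method 1 (detected, not), row 2 = method 2."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for value in (self.a, self.b, self.c, self.d):
            if value < 0:
                raise ValueError(f"contingency counts must be non-negative, got {value}")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("contingency table is all zero")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def fisher_exact_two_sided(table: ContingencyTable2x2) -> float:
    """Exact two-sided p-value for a 2x2 table, in (0, 1]."""
    if not isinstance(table, ContingencyTable2x2):
        table = ContingencyTable2x2(*table)
    return float(_scipy_fisher([[table.a, table.b], [table.c, table.d]]).pvalue)


def _as_bool(status) -> bool:
    if isinstance(status, bool):
        return status
    if isinstance(status, (int,)):
        return bool(status)
    text = str(status).strip().lower()
    if text in ("positive", "pos", "true", "1", "yes"):
        return True
    if text in ("negative", "neg", "false", "0", "no"):
        return False
    raise ValueError(f"cannot interpret status {status!r}")


@dataclass(frozen=True)
class ConfusionSummary:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float | None
    specificity: float | None

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


def confusion_summary(
    calls: Iterable[tuple[str, object]],
    truth: Iterable[tuple[str, object]] | Mapping[str, object],
) -> ConfusionSummary:
    """Sensitivity and specificity of predicted against true status.

    Undefined ratios (no positives or no negatives in truth) are reported
    as ``None``, never as 0.
    """
    truth_map = dict(truth.items()) if isinstance(truth, Mapping) else dict(truth)
    calls = list(calls)
    missing = sorted({sid for sid, _ in calls} - set(truth_map))
    if missing:
        raise DataError(f"samples missing from truth: {', '.join(missing)}")
    tp = fp = tn = fn = 0
    for sid, predicted in calls:
        pred = _as_bool(predicted)
        true = _as_bool(truth_map[sid])
        if true and pred:
            tp += 1
        elif true and not pred:
            fn += 1
        elif not true and pred:
            fp += 1
        else:
            tn += 1
    sensitivity = tp / (tp + fn) if (tp + fn) > 0 else None
    specificity = tn / (tn + fp) if (tn + fp) > 0 else None
    return ConfusionSummary(tp=tp, fp=fp, tn=tn, fn=fn, sensitivity=sensitivity, specificity=specificity)
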