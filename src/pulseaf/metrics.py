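"""Classification metrics and the ET-score evaluation system.

Recall, precision and F-measure are carried as percentages at full
precision; rounding (half-up, 2 decimals) happens only at report
boundaries.  AF is the positive class.

The ET-score combines detection quality with computational speed: the
F-measure term ``(beta^2 + 1) * F_AF * F_NSR / (beta^2 * (F_AF + F_NSR))``
(the harmonic mean of the two per-class F-measures when beta = 1) is scaled
by a time factor determined by each method's speed rank — the fastest
method gets 1.00, and the factor drops by 0.02 per rank, flooring at 0.02.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def round_half_up(x: float, decimals: int = 2) -> float:
    """Decimal half-up rounding as used in printed report tables."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts with AF as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class ClassMetrics:
    recall: float
    precision: float
    f_measure: float


@dataclass(frozen=True)
class MethodTiming:
    method_name: str
    speed_rank: int
    time_factor: float
    measured_time_s: float | None = None


@dataclass
class ETScoreReport:
    """One row of a method-comparison table."""

    method_name: str
    f_af: float
    f_nsr: float
    time_factor: float
    et_score: float
    beta: float = 1.0


def confusion(labels: list[str], predictions: list[str]) -> ConfusionMatrix:
    """Tally AF-positive confusion counts from parallel label lists."""
    if len(labels) != len(predictions):
        raise ValueError("labels and predictions must have equal length")
    tp = fp = fn = tn = 0
    for truth, pred in zip(labels, predictions):
        if truth not in ("AF", "NSR") or pred not in ("AF", "NSR"):
            raise ValueError(f"labels must be 'AF' or 'NSR', got ({truth!r}, {pred!r})")
        if truth == "AF":
            tp += pred == "AF"
            fn += pred == "NSR"
        else:
            tn += pred == "NSR"
            fp += pred == "AF"
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def f_measure(recall: float, precision: float) -> float:
    """Harmonic mean of recall and precision (percent in, percent out)."""
    if recall + precision == 0:
        return 0.0
    return 2.0 * recall * precision / (recall + precision)


def class_metrics(cm: ConfusionMatrix, positive: str = "AF") -> ClassMetrics:
    """Recall, precision and F-measure (percent) for one class.

    Zero denominators yield 0 with a warning rather than an error.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    if positive == "AF":
        tp, fp, fn = cm.tp, cm.fp, cm.fn
    elif positive == "NSR":
        tp, fp, fn = cm.tn, cm.fn, cm.fp
    else:
        raise ValueError("positive must be 'AF' or 'NSR'")
    if tp + fn == 0 or tp + fp == 0:
        logger.warning("zero denominator in recall/precision for class %s", positive)
    recall = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    precision = 100.0 * tp / (tp + fp) if tp + fp else 0.0
    return ClassMetrics(recall=recall, precision=precision, f_measure=f_measure(recall, precision))


def rank_time_factor(speed_rank: int) -> float:
    """Fastest rank 1 -> 1.00, each further rank -0.02, floored at 0.02."""
    if speed_rank < 1:
        raise ValueError("speed_rank is 1-based")
    return max((100.0 - 2.0 * (speed_rank - 1)) / 100.0, 0.02)


def time_factors(methods: list[tuple[str, float]]) -> list[MethodTiming]:
    """Rank methods by measured time (ascending); ties break by name order."""
    if not methods:
        raise ValueError("need at least one method")
    times = [t for _, t in methods]
    if len(set(times)) < len(times):
        logger.warning("tied measured times; breaking ties by input order")
    order = sorted(range(len(methods)), key=lambda k: (methods[k][1], k))
    out: list[MethodTiming | None] = [None] * len(methods)
    for rank0, k in enumerate(order):
        name, t = methods[k]
        out[k] = MethodTiming(
            method_name=name,
            speed_rank=rank0 + 1,
            time_factor=rank_time_factor(rank0 + 1),
            measured_time_s=t,
        )
    return out  # type: ignore[return-value]


def et_score(f_af: float, f_nsr: float, time_factor: float, beta: float = 1.0) -> float:
    """(beta^2+1) * F_AF * F_NSR / (beta^2 * (F_AF + F_NSR)) * time_factor.

    F-measures are percentages in [0, 100]; the time factor lies in (0, 1].
    Reported values are rounded half-up to 2 decimals by callers; this
    function returns full precision.
    """
    for name, f in (("f_af", f_af), ("f_nsr", f_nsr)):
        if not 0 <= f <= 100:
            raise ValueError(f"{name} must lie in [0, 100], got {f}")
    if not 0 < time_factor <= 1:
        raise ValueError(f"time_factor must lie in (0, 1], got {time_factor}")
    if f_af + f_nsr == 0:
        return 0.0
    return (beta**2 + 1.0) * f_af * f_nsr / (beta**2 * (f_af + f_nsr)) * time_factor


def accuracy(cm: ConfusionMatrix) -> float:
    """Overall accuracy in percent from a confusion matrix."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * (cm.tp + cm.tn) / cm.total


def accuracy_from_recalls(recalls: dict[str, float], prevalences: dict[str, float]) -> float:
    """Prevalence-weighted mean of per-class recalls (all in percent).

    ``prevalences`` may be given in percent or as fractions; they are
    normalized to sum to 1.
    """
    if set(recalls) != set(prevalences):
        raise ValueError("recalls and prevalences must cover the same classes")
    w = np.array([prevalences[k] for k in recalls], dtype=float)
    if w.sum() <= 0:
        raise ValueError("prevalences must sum to a positive value")
    w = w / w.sum()
    r = np.array([recalls[k] for k in recalls], dtype=float)
    return float(np.sum(w * r))


def compare_methods(
    results: list[tuple[str, ConfusionMatrix, float | None]],
    ranks: dict[str, int] | None = None,
    beta: float = 1.0,
) -> list[ETScoreReport]:
    """Per-method F_AF, F_NSR and ET-score, sorted by ET-score descending.

    Speed ranks come from measured times unless supplied directly via
    ``ranks``.
    """
    if len(results) < 2:
        raise ValueError("method comparison needs at least 2 methods")
    if ranks is None:
        timed = [(name, t) for name, _, t in results]
        if any(t is None for _, t in timed):
            raise ValueError("either measured times for all methods or explicit ranks")
        factor = {mt.method_name: mt.time_factor for mt in time_factors(timed)}
    else:
        factor = {name: rank_time_factor(r) for name, r in ranks.items()}
    rows = []
    for name, cm, _t in results:
        f_af = class_metrics(cm, "AF").f_measure
        f_nsr = class_metrics(cm, "NSR").f_measure
        rows.append(
            ETScoreReport(
                method_name=name,
                f_af=f_af,
                f_nsr=f_nsr,
                time_factor=factor[name],
                et_score=et_score(f_af, f_nsr, factor[name], beta),
                beta=beta,
            )
        )
    rows.sort(key=lambda r: r.et_score, reverse=True)
    return rows


def report_frame(rows: list[ETScoreReport]) -> pd.DataFrame:
    """Report table with percentages rounded half-up to 2 decimals."""
    return pd.DataFrame(
        [
            {
                "method": r.method_name,
                "F_AF_pct": round_half_up(r.f_af),
                "F_NSR_pct": round_half_up(r.f_nsr),
                "time_factor": r.time_factor,
                "ET_score": round_half_up(r.et_score),
            }
            for r in rows
        ]
    )
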