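"""Confusion-matrix accounting and scalar screening-accuracy metrics.

The screening question is binary: does the analyser flag the sample for
culture (screen-positive) or screen it out (screen-negative), and does the
culture confirm significant bacteriuria (truth)?  Everything downstream —
sensitivity, specificity, predictive values, accuracy — derives from the
2×2 confusion matrix, plus one workload quantity specific to screening-out:

    reduction = (TN + FN) / N

the fraction of samples a laboratory would *not* culture under the rule.
A screen is useful when reduction is large while sensitivity stays at or
above the 90–95% guideline level, so that almost no culture-positive
sample is screened out.

Predictive values depend on prevalence through Bayes' rule; the
:func:`rates_to_predictive_values` identities let printed (Se, Sp,
prevalence) triples be audited without per-sample data, and are
algebraically identical to :func:`metrics_from_confusion` on any matrix
with those rates.

All arithmetic keeps full precision; percentages are rounded half-up only
in the report layer (:func:`pct`).  Metrics with a zero denominator are
explicit ``None`` flags, never silently 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields
from decimal import ROUND_HALF_UP, Decimal
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ConfusionMatrix",
    "MetricSet",
    "PredictiveValues",
    "ContractError",
    "confusion_from_predictions",
    "metrics_from_confusion",
    "rates_to_predictive_values",
    "proportion_ci",
    "pct",
]


class ContractError(ValueError):
    """An argument violates an operation's contract."""


def pct(proportion: float | None, decimals: int = 1) -> float | None:
    """Percentage view of a proportion, rounded half-up (report layer only)."""
    if proportion is None:
        return None
    quantum = Decimal(10) ** -decimals
    value = Decimal(repr(float(proportion) * 100.0))
    return float(value.quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FP/TN/FN counts for a screening rule against culture truth."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if int(value) != value or value < 0:
                raise ContractError(f"{f.name} must be a non-negative integer, got {value!r}")
            object.__setattr__(self, f.name, int(value))
        if self.total < 1:
            raise ContractError("confusion matrix must count at least one sample")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def positives(self) -> int:
        """Truth positives (culture-positive samples)."""
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        """Truth negatives."""
        return self.tn + self.fp


@dataclass(frozen=True)
class MetricSet:
    """Scalar accuracy metrics as proportions in [0, 1].

    ``None`` marks a metric whose denominator was zero (undefined), e.g.
    PPV when nothing screened positive.  ``reduction`` is the screened-out
    fraction (TN+FN)/N — the cultures avoided.
    """

    se: float | None
    sp: float | None
    ppv: float | None
    npv: float | None
    accuracy: float | None
    reduction: float | None
    prevalence: float | None

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if value is not None and not (0.0 <= value <= 1.0):
                raise ContractError(f"{f.name} must lie in [0, 1], got {value!r}")

    def to_dict(self, percentages: bool = True) -> dict[str, float | None]:
        out = {f.name: getattr(self, f.name) for f in fields(self)}
        if percentages:
            out.update({f"{k}_pct": pct(v) for k, v in list(out.items())})
        return out

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def to_frame(self) -> pd.DataFrame:
        """One-row frame with proportion columns plus *_pct views."""
        return pd.DataFrame([self.to_dict()])


class PredictiveValues(NamedTuple):
    ppv: float | None
    npv: float | None
    reduction: float
    accuracy: float


def confusion_from_predictions(
    truth: Sequence[bool] | np.ndarray,
    screen: Sequence[bool] | np.ndarray,
) -> ConfusionMatrix:
    """Tally the 2×2 table from per-sample truth and screen labels."""
    t = np.asarray(truth, dtype=bool)
    s = np.asarray(screen, dtype=bool)
    if t.shape != s.shape or t.ndim != 1:
        raise ContractError(
            f"truth and screen must be 1-d and equal length, got {t.shape} vs {s.shape}"
        )
    if t.size < 1:
        raise ContractError("need at least one sample")
    return ConfusionMatrix(
        tp=int(np.sum(t & s)),
        fp=int(np.sum(~t & s)),
        tn=int(np.sum(~t & ~s)),
        fn=int(np.sum(t & ~s)),
    )


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricSet:
    """All scalar metrics of a confusion matrix, full precision.

    se = TP/(TP+FN), sp = TN/(TN+FP), ppv = TP/(TP+FP), npv = TN/(TN+FN),
    accuracy = (TP+TN)/N, reduction = (TN+FN)/N, prevalence = (TP+FN)/N.
    """
    n = cm.total
    return MetricSet(
        se=_ratio(cm.tp, cm.positives),
        sp=_ratio(cm.tn, cm.negatives),
        ppv=_ratio(cm.tp, cm.tp + cm.fp),
        npv=_ratio(cm.tn, cm.tn + cm.fn),
        accuracy=(cm.tp + cm.tn) / n,
        reduction=(cm.tn + cm.fn) / n,
        prevalence=cm.positives / n,
    )


def rates_to_predictive_values(
    se: float, sp: float, prevalence: float
) -> PredictiveValues:
    """Bayes-rule predictive values and workload metrics from (Se, Sp, p).

    ppv = Se·p / (Se·p + (1−Sp)(1−p))
    npv = Sp(1−p) / (Sp(1−p) + (1−Se)p)
    reduction = Sp(1−p) + (1−Se)p          (screen-negative fraction)
    accuracy  = Se·p + Sp(1−p)

    Identical to :func:`metrics_from_confusion` on any confusion matrix
    realising those rates; useful for auditing published operating points
    when per-sample data are unavailable.
    """
    for name, value in (("se", se), ("sp", sp), ("prevalence", prevalence)):
        if not (0.0 <= value <= 1.0):
            raise ContractError(f"{name} must lie in [0, 1], got {value!r}")
    q = 1.0 - prevalence
    screen_pos = se * prevalence + (1.0 - sp) * q
    screen_neg = sp * q + (1.0 - se) * prevalence
    ppv = se * prevalence / screen_pos if screen_pos > 0 else None
    npv = sp * q / screen_neg if screen_neg > 0 else None
    return PredictiveValues(
        ppv=ppv,
        npv=npv,
        reduction=screen_neg,
        accuracy=se * prevalence + sp * q,
    )


def proportion_ci(
    successes: int, trials: int, level: float = 0.95
) -> tuple[float, float]:
    """Wilson score confidence interval for a binomial proportion."""
    if not (0 < level < 1):
        raise ContractError(f"level must lie in (0, 1), got {level!r}")
    if trials < 1 or not (0 <= successes <= trials):
        raise ContractError(
            f"need 0 <= successes <= trials with trials >= 1, got {successes}/{trials}"
        )
    lo, hi = proportion_confint(successes, trials, alpha=1.0 - level, method="wilson")
    return (max(0.0, float(lo)), min(1.0, float(hi)))
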