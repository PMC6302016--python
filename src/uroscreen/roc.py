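"""Empirical ROC curves, AUC and single-marker cut-off selection.

One analyser channel (bacteria/μL or WBC/μL) is a continuous marker for
culture truth.  The decision convention throughout is *screen-positive iff
value >= threshold*: analyser cut-offs are "flag at or above" levels.
Candidate thresholds are the observed values themselves plus +inf (the
all-negative sentinel), so a reported cut-off is always a realizable
machine reading rather than an interpolated midpoint.

AUC is the trapezoidal area under (FPR, Se), which with the ≥ convention
and ties scored ½ equals the rank statistic
P(X_pos > X_neg) + ½·P(X_pos = X_neg).

Two selection criteria are offered:

``youden``
    maximize Se + Sp − 1 (balance criterion);
``se_floor`` (with a target, e.g. 0.95)
    maximize Sp subject to Se >= target — the screening framing, where
    guidelines ask for sensitivity above 90–95% and specificity buys
    workload reduction.

Ties in the criterion are broken deterministically: prefer higher Se, then
the higher (stricter) threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sk_roc_curve

from .metrics import ConfusionMatrix, ContractError, MetricSet, metrics_from_confusion

__all__ = [
    "RocPoint",
    "RocCurve",
    "CutoffResult",
    "build_roc",
    "auc",
    "best_single_cutoff",
    "threshold_metrics",
]


@dataclass(frozen=True)
class RocPoint:
    threshold: float
    se: float
    fpr: float


@dataclass(frozen=True)
class RocCurve:
    """Operating points ordered by decreasing threshold, with AUC.

    The first point is the +inf sentinel (se=0, fpr=0); the last flags
    every sample (se=1, fpr=1).  se and fpr are non-decreasing.
    """

    points: tuple[RocPoint, ...]
    auc: float

    @property
    def thresholds(self) -> np.ndarray:
        return np.array([p.threshold for p in self.points])

    @property
    def se(self) -> np.ndarray:
        return np.array([p.se for p in self.points])

    @property
    def fpr(self) -> np.ndarray:
        return np.array([p.fpr for p in self.points])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds, "se": self.se, "fpr": self.fpr})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def plot(self, path: str | Path, label: str | None = None) -> None:
        """Write a Se vs 1−Sp plot (PNG/SVG by extension)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4.5, 4.5))
        ax.plot(self.fpr, self.se, drawstyle="steps-post",
                label=f"{label or 'marker'} (AUC={self.auc:.3f})")
        ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
        ax.set_xlabel("1 − specificity")
        ax.set_ylabel("sensitivity")
        ax.legend(loc="lower right")
        fig.tight_layout()
        fig.savefig(path)
        plt.close(fig)


@dataclass(frozen=True)
class CutoffResult:
    """A selected operating threshold with its full metric set."""

    threshold: float
    metrics: MetricSet
    criterion: str


def _validate_marker(values, truth) -> tuple[np.ndarray, np.ndarray]:
    v = np.asarray(values, dtype=float)
    t = np.asarray(truth, dtype=bool)
    if v.shape != t.shape or v.ndim != 1 or v.size < 1:
        raise ContractError("values and truth must be 1-d and equal length")
    if not (t.any() and (~t).any()):
        raise ContractError("ROC needs at least one positive and one negative sample")
    return v, t


def build_roc(values: Sequence[float], truth: Sequence[bool]) -> RocCurve:
    """Empirical ROC of one marker against culture truth.

    One point per distinct observed value plus the +inf sentinel; tied
    values produce a single point (no interpolation within a tie).
    """
    v, t = _validate_marker(values, truth)
    fpr, se, thresholds = _sk_roc_curve(t, v, drop_intermediate=False)
    points = tuple(
        RocPoint(threshold=float(th), se=float(s), fpr=float(f))
        for th, s, f in zip(thresholds, se, fpr)
    )
    return RocCurve(points=points, auc=float(np.trapezoid(se, fpr)))


def auc(curve: RocCurve) -> float:
    """Trapezoidal area under (fpr, se); ties carry ½ credit by construction."""
    return float(np.trapezoid(curve.se, curve.fpr))


def _candidate_rates(v: np.ndarray, t: np.ndarray):
    """se/sp at every candidate threshold (distinct values desc + inf first).

    Returns (thresholds, se, sp, tp, fp) arrays with the +inf sentinel at
    index 0, using the value >= threshold convention.
    """
    n_pos = int(t.sum())
    n_neg = int(t.size - n_pos)
    order = np.argsort(v, kind="stable")[::-1]
    v_sorted = v[order]
    t_sorted = t[order]
    distinct = np.r_[True, v_sorted[1:] != v_sorted[:-1]]
    # cumulative counts at each sorted position, collapsed to distinct values
    tp_cum = np.cumsum(t_sorted)
    fp_cum = np.cumsum(~t_sorted)
    last_of_value = np.r_[distinct[1:], True]
    thresholds = np.r_[np.inf, v_sorted[last_of_value]]
    tp = np.r_[0, tp_cum[last_of_value]]
    fp = np.r_[0, fp_cum[last_of_value]]
    se = tp / n_pos
    sp = (n_neg - fp) / n_neg
    return thresholds, se, sp, tp, fp


def threshold_metrics(
    values: Sequence[float], truth: Sequence[bool], threshold: float
) -> MetricSet:
    """Full metric set of the single-marker rule value >= threshold."""
    v, t = _validate_marker(values, truth)
    screen = v >= threshold
    cm = ConfusionMatrix(
        tp=int(np.sum(t & screen)),
        fp=int(np.sum(~t & screen)),
        tn=int(np.sum(~t & ~screen)),
        fn=int(np.sum(t & ~screen)),
    )
    return metrics_from_confusion(cm)


def _select(thresholds, se, sp, scores) -> int:
    """Index of the best candidate; ties → higher se, then higher threshold."""
    best = np.max(scores)
    mask = scores == best
    se_best = np.max(se[mask])
    mask &= se == se_best
    idx = np.nonzero(mask)[0]
    return int(idx[np.argmax(thresholds[idx])])


def best_single_cutoff(
    values: Sequence[float],
    truth: Sequence[bool],
    criterion: str = "youden",
    se_target: float | None = None,
) -> CutoffResult:
    """Criterion-optimal single-marker cut-off over the candidate set.

    ``criterion="youden"`` maximizes Se + Sp − 1; ``criterion="se_floor"``
    maximizes Sp subject to Se >= ``se_target``.

    Raises :class:`ContractError` when the floor is unachievable, naming
    the maximum achievable sensitivity.
    """
    v, t = _validate_marker(values, truth)
    thresholds, se, sp, _, _ = _candidate_rates(v, t)
    if criterion == "youden":
        scores = se + sp - 1.0
        label = "youden"
    elif criterion == "se_floor":
        if se_target is None or not (0.0 < se_target <= 1.0):
            raise ContractError(f"se_floor needs a target in (0, 1], got {se_target!r}")
        feasible = se >= se_target
        if not feasible.any():
            raise ContractError(
                f"se floor {se_target} unachievable; max achievable se = {se.max():.4f}"
            )
        scores = np.where(feasible, sp, -np.inf)
        label = f"se_floor({se_target})"
    else:
        raise ContractError(f"unknown criterion {criterion!r}")
    i = _select(thresholds, se, sp, scores)
    return CutoffResult(
        threshold=float(thresholds[i]),
        metrics=threshold_metrics(v, t, thresholds[i]),
        criterion=label,
    )
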