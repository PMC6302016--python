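"""Combined bacteria-OR-leukocyte screening rules and their optimization.

The combined screen flags a sample for culture when *either* channel is at
or above its cut-off:

    screen-positive  iff  bacteria/μL >= t_bac  OR  WBC/μL >= t_wbc.

The OR combiner can only add flagged samples relative to either channel
alone, so its sensitivity dominates both single-marker rules and its
specificity is dominated by both — the trade the screening laboratory
wants, since a missed culture-positive is the costly error.  Setting one
threshold to +inf degrades the rule to a single-marker screen.

Optimization is an exhaustive search over the product grid of candidate
thresholds (observed values per channel, plus +inf).  The whole grid is
evaluated at once from a 2-D cumulative count table: for thresholds
(t_b, t_w) the flagged count is  N − #{bacteria < t_b AND wbc < t_w},
so one padded 2-D cumulative sum per truth class yields TP and FP for
every pair simultaneously — O(|grid_bac|·|grid_wbc|) cells, no per-rule
pass over the samples.

Criterion ties break deterministically: higher se, then higher t_bac,
then higher t_wbc (the stricter rule at equal performance).

An AND combiner (flag only when both channels exceed their cut-offs) is
exposed behind the ``combiner`` flag for completeness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .metrics import ConfusionMatrix, ContractError, MetricSet, metrics_from_confusion
from .samples_io import Cohort, CultureLabelConfig, UrineSample

__all__ = [
    "DualThresholdRule",
    "ParetoSet",
    "apply_rule",
    "apply_rule_to_counts",
    "optimize_dual",
    "optimize_dual_counts",
    "pareto_front",
    "pareto_front_counts",
]


@dataclass(frozen=True)
class DualThresholdRule:
    """Two channel cut-offs (counts/μL) with a fixed combiner.

    ``t_bac`` / ``t_wbc`` may be +inf, silencing that channel.
    """

    t_bac: float
    t_wbc: float
    combiner: str = "or"

    def __post_init__(self) -> None:
        if self.combiner not in ("or", "and"):
            raise ContractError(f"combiner must be 'or' or 'and', got {self.combiner!r}")
        for name in ("t_bac", "t_wbc"):
            value = getattr(self, name)
            if math.isnan(value):
                raise ContractError(f"{name} may not be NaN")

    def to_dict(self) -> dict:
        return {"t_bac": self.t_bac, "t_wbc": self.t_wbc, "combiner": self.combiner}


@dataclass(frozen=True)
class ParetoSet:
    """Nondominated (se, sp) operating points over the threshold grid."""

    rules: tuple[tuple[DualThresholdRule, MetricSet], ...]

    def __len__(self) -> int:
        return len(self.rules)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rule, m in self.rules:
            rows.append({"t_bac": rule.t_bac, "t_wbc": rule.t_wbc,
                         "se": m.se, "sp": m.sp, "ppv": m.ppv, "npv": m.npv,
                         "reduction": m.reduction})
        return pd.DataFrame(rows)


def apply_rule(sample: UrineSample, rule: DualThresholdRule) -> bool:
    """Screen label of one sample under the rule."""
    return bool(
        apply_rule_to_counts(
            np.array([sample.bacteria_per_uL]), np.array([sample.wbc_per_uL]), rule
        )[0]
    )


def apply_rule_to_counts(
    bacteria: Sequence[float], wbc: Sequence[float], rule: DualThresholdRule
) -> np.ndarray:
    """Vectorized screen labels for count arrays."""
    b = np.asarray(bacteria, dtype=float)
    w = np.asarray(wbc, dtype=float)
    if b.shape != w.shape:
        raise ContractError("bacteria and wbc arrays must have equal shape")
    if np.isnan(b).any() or np.isnan(w).any():
        raise ContractError("missing counts: both channels are required")
    if rule.combiner == "or":
        return (b >= rule.t_bac) | (w >= rule.t_wbc)
    return (b >= rule.t_bac) & (w >= rule.t_wbc)


# ---------------------------------------------------------------- grid core

def _grid_tables(b: np.ndarray, w: np.ndarray, t: np.ndarray, combiner: str):
    """TP and FP over the full product grid of candidate thresholds.

    Returns (tb_grid, tw_grid, TP, FP) where tb_grid/tw_grid are the
    ascending distinct values with +inf appended, and TP[i, j] counts
    truth-positives flagged by the rule (tb_grid[i], tw_grid[j]).
    """
    vb = np.unique(b)
    vw = np.unique(w)
    ib = np.searchsorted(vb, b)
    iw = np.searchsorted(vw, w)
    nb, nw = vb.size, vw.size

    def padded_cumulative(mask: np.ndarray) -> np.ndarray:
        # P[i, j] = #{samples in mask with value_b < grid_b[i] and value_w < grid_w[j]}
        counts = np.zeros((nb, nw), dtype=np.int32)
        np.add.at(counts, (ib[mask], iw[mask]), 1)
        out = np.zeros((nb + 1, nw + 1), dtype=np.int32)
        np.cumsum(counts, axis=0, out=counts)
        np.cumsum(counts, axis=1, out=counts)
        out[1:, 1:] = counts
        return out

    below_pos = padded_cumulative(t)
    below_neg = padded_cumulative(~t)
    n_pos = int(t.sum())
    n_neg = int(t.size - n_pos)
    if combiner == "or":
        tp = n_pos - below_pos
        fp = n_neg - below_neg
    else:  # and: flagged = total - below_b - below_w + below_both
        marg_b_pos = below_pos[:, -1][:, None]
        marg_w_pos = below_pos[-1, :][None, :]
        marg_b_neg = below_neg[:, -1][:, None]
        marg_w_neg = below_neg[-1, :][None, :]
        tp = n_pos - marg_b_pos - marg_w_pos + below_pos
        fp = n_neg - marg_b_neg - marg_w_neg + below_neg
    tb_grid = np.r_[vb, np.inf]
    tw_grid = np.r_[vw, np.inf]
    return tb_grid, tw_grid, tp, fp


def _validate_counts(bacteria, wbc, truth):
    b = np.asarray(bacteria, dtype=float)
    w = np.asarray(wbc, dtype=float)
    t = np.asarray(truth, dtype=bool)
    if not (b.shape == w.shape == t.shape) or b.ndim != 1 or b.size < 1:
        raise ContractError("bacteria, wbc and truth must be 1-d and equal length")
    if not (t.any() and (~t).any()):
        raise ContractError("optimization needs at least one positive and one negative")
    return b, w, t


def _rule_metrics(b, w, t, rule: DualThresholdRule) -> MetricSet:
    screen = apply_rule_to_counts(b, w, rule)
    return metrics_from_confusion(ConfusionMatrix(
        tp=int(np.sum(t & screen)), fp=int(np.sum(~t & screen)),
        tn=int(np.sum(~t & ~screen)), fn=int(np.sum(t & ~screen)),
    ))


def optimize_dual_counts(
    bacteria: Sequence[float],
    wbc: Sequence[float],
    truth: Sequence[bool],
    criterion: str = "se_floor",
    se_target: float | None = 0.95,
    combiner: str = "or",
) -> tuple[DualThresholdRule, MetricSet]:
    """Criterion-optimal dual rule by exhaustive product-grid search.

    Array-level core of :func:`optimize_dual`; see there for semantics.
    """
    b, w, t = _validate_counts(bacteria, wbc, truth)
    tb_grid, tw_grid, tp, fp = _grid_tables(b, w, t, combiner)
    n_pos = int(t.sum())
    n_neg = t.size - n_pos
    se = tp / n_pos
    sp = (n_neg - fp) / n_neg

    if criterion == "youden":
        scores = se + sp - 1.0
    elif criterion == "se_floor":
        if se_target is None or not (0.0 < se_target <= 1.0):
            raise ContractError(f"se_floor needs a target in (0, 1], got {se_target!r}")
        feasible = se >= se_target
        if not feasible.any():
            raise ContractError(
                f"se floor {se_target} unachievable; max achievable se = {se.max():.4f}"
            )
        scores = np.where(feasible, sp, -np.inf)
    else:
        raise ContractError(f"unknown criterion {criterion!r}")

    # ties: higher se, then higher t_bac, then higher t_wbc
    mask = scores == np.max(scores)
    mask &= se == np.max(se[mask])
    i_cands, j_cands = np.nonzero(mask)
    i = i_cands.max()
    j = j_cands[i_cands == i].max()
    rule = DualThresholdRule(
        t_bac=float(tb_grid[i]), t_wbc=float(tw_grid[j]), combiner=combiner
    )
    return rule, _rule_metrics(b, w, t, rule)


def optimize_dual(
    cohort: Cohort,
    criterion: str = "se_floor",
    se_target: float | None = 0.95,
    combiner: str = "or",
    label_config: CultureLabelConfig | None = None,
) -> tuple[DualThresholdRule, MetricSet]:
    """Jointly optimal (t_bac, t_wbc) for a cohort under a criterion.

    ``criterion="youden"`` maximizes Se + Sp − 1; ``"se_floor"`` (default,
    target 0.95) maximizes Sp subject to Se >= target, the screening
    framing in which the rule must almost never screen out a
    culture-positive sample.  Every pair from the product grid of observed
    values (plus +inf per channel) is evaluated; ties break toward higher
    se, then higher t_bac, then higher t_wbc.
    """
    cohort.require_nonempty()
    return optimize_dual_counts(
        cohort.bacteria, cohort.wbc, cohort.truth_labels(label_config),
        criterion=criterion, se_target=se_target, combiner=combiner,
    )


def pareto_front_counts(
    bacteria: Sequence[float],
    wbc: Sequence[float],
    truth: Sequence[bool],
    combiner: str = "or",
) -> ParetoSet:
    """All nondominated (se, sp) grid points; array-level core."""
    b, w, t = _validate_counts(bacteria, wbc, truth)
    tb_grid, tw_grid, tp, fp = _grid_tables(b, w, t, combiner)
    n_pos = int(t.sum())
    n_neg = t.size - n_pos
    se = (tp / n_pos).ravel()
    sp = ((n_neg - fp) / n_neg).ravel()
    ii, jj = np.meshgrid(np.arange(tb_grid.size), np.arange(tw_grid.size), indexing="ij")
    ii, jj = ii.ravel(), jj.ravel()
    # order by se desc, sp desc, then stricter rules first (tie-break)
    order = np.lexsort((-jj, -ii, -sp, -se))
    kept: list[tuple[DualThresholdRule, MetricSet]] = []
    best_sp = -1.0
    seen: set[tuple[float, float]] = set()
    for k in order:
        point = (se[k], sp[k])
        if sp[k] > best_sp and point not in seen:
            seen.add(point)
            best_sp = sp[k]
            rule = DualThresholdRule(
                t_bac=float(tb_grid[ii[k]]), t_wbc=float(tw_grid[jj[k]]), combiner=combiner
            )
            kept.append((rule, _rule_metrics(b, w, t, rule)))
    return ParetoSet(rules=tuple(kept))


def pareto_front(
    cohort: Cohort,
    combiner: str = "or",
    label_config: CultureLabelConfig | None = None,
) -> ParetoSet:
    """Nondominated sensitivity/specificity frontier of all dual rules."""
    cohort.require_nonempty()
    return pareto_front_counts(
        cohort.bacteria, cohort.wbc, cohort.truth_labels(label_config), combiner=combiner
    )
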