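"""End-to-end evaluation reports and two-device comparison at matched sensitivity.

:func:`evaluate` runs one screening rule against one cohort and packages
the confusion-derived metrics, Wilson confidence intervals, and a cohort
summary into a serializable report.  Percentage fields in the serialized
report are rounded views; the underlying proportions keep full precision.

:func:`compare_devices` is the decision-making primitive: each device's
cohort is optimized *independently* under the same sensitivity floor
(matched sensitivity, not matched threshold — analysers with different
count scales cannot share thresholds), and the specificity and
culture-reduction differences are reported with seeded bootstrap
percentile intervals (samples resampled with replacement, the chosen
rules held fixed).  The study design this mirrors reports no uncertainty;
the bootstrap is this package's addition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dual_rule import DualThresholdRule, apply_rule_to_counts, optimize_dual_counts
from .metrics import (
    ConfusionMatrix,
    ContractError,
    MetricSet,
    metrics_from_confusion,
    pct,
    proportion_ci,
)
from .samples_io import Cohort, CultureLabelConfig

__all__ = [
    "CohortSummary",
    "EvaluationReport",
    "DeviceComparison",
    "evaluate",
    "compare_devices",
]


@dataclass(frozen=True)
class CohortSummary:
    n: int
    positives: int
    negatives: int
    contaminated: int

    def __post_init__(self) -> None:
        if self.positives + self.negatives != self.n:
            raise ContractError("cohort summary counts must sum to n")


@dataclass(frozen=True)
class EvaluationReport:
    """One rule, one cohort: metrics, intervals and summary, serializable."""

    device: str
    culture_threshold: float
    rule: DualThresholdRule
    metrics: MetricSet
    intervals: dict[str, tuple[float, float]]
    cohort_summary: CohortSummary

    def to_dict(self) -> dict:
        return {
            "device": self.device,
            "culture_threshold": self.culture_threshold,
            "rule": self.rule.to_dict(),
            "metrics": self.metrics.to_dict(),
            "intervals": {k: list(v) for k, v in self.intervals.items()},
            "cohort_summary": {
                "n": self.cohort_summary.n,
                "positives": self.cohort_summary.positives,
                "negatives": self.cohort_summary.negatives,
                "contaminated": self.cohort_summary.contaminated,
            },
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, data: dict) -> "EvaluationReport":
        metric_fields = ("se", "sp", "ppv", "npv", "accuracy", "reduction", "prevalence")
        return cls(
            device=data["device"],
            culture_threshold=data["culture_threshold"],
            rule=DualThresholdRule(**data["rule"]),
            metrics=MetricSet(**{k: data["metrics"][k] for k in metric_fields}),
            intervals={k: tuple(v) for k, v in data["intervals"].items()},
            cohort_summary=CohortSummary(**data["cohort_summary"]),
        )

    @classmethod
    def from_json(cls, text: str) -> "EvaluationReport":
        return cls.from_dict(json.loads(text))


def _confusion(cohort: Cohort, rule: DualThresholdRule,
               config: CultureLabelConfig) -> ConfusionMatrix:
    truth = cohort.truth_labels(config)
    screen = apply_rule_to_counts(cohort.bacteria, cohort.wbc, rule)
    return ConfusionMatrix(
        tp=int(np.sum(truth & screen)), fp=int(np.sum(~truth & screen)),
        tn=int(np.sum(~truth & ~screen)), fn=int(np.sum(truth & ~screen)),
    )


def evaluate(
    cohort: Cohort,
    rule: DualThresholdRule,
    culture_config: CultureLabelConfig | None = None,
    ci_level: float = 0.95,
) -> EvaluationReport:
    """Deterministic evaluation of one rule on one cohort.

    Wilson intervals are attached for se, sp, ppv, npv, accuracy and
    reduction (each over its natural denominator).
    """
    cohort.require_nonempty()
    config = culture_config or cohort.label_config
    cm = _confusion(cohort, rule, config)
    metrics = metrics_from_confusion(cm)
    n = cm.total
    numerators = {
        "se": (cm.tp, cm.positives),
        "sp": (cm.tn, cm.negatives),
        "ppv": (cm.tp, cm.tp + cm.fp),
        "npv": (cm.tn, cm.tn + cm.fn),
        "accuracy": (cm.tp + cm.tn, n),
        "reduction": (cm.tn + cm.fn, n),
    }
    intervals = {
        name: proportion_ci(k, m, ci_level)
        for name, (k, m) in numerators.items() if m > 0
    }
    device = cohort.samples[0].device if cohort.samples else "unknown"
    return EvaluationReport(
        device=device,
        culture_threshold=config.cfu_threshold,
        rule=rule,
        metrics=metrics,
        intervals=intervals,
        cohort_summary=CohortSummary(
            n=n, positives=cm.positives, negatives=cm.negatives,
            contaminated=sum(s.contaminated for s in cohort.samples),
        ),
    )


@dataclass(frozen=True)
class DeviceComparison:
    """Side-by-side operating points at matched sensitivity, with uncertainty."""

    se_target: float
    report_a: EvaluationReport
    report_b: EvaluationReport
    sp_diff: float
    reduction_diff: float
    sp_diff_ci: tuple[float, float]
    reduction_diff_ci: tuple[float, float]
    n_bootstrap: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "se_target": self.se_target,
            "device_a": self.report_a.to_dict(),
            "device_b": self.report_b.to_dict(),
            "sp_diff": self.sp_diff,
            "sp_diff_pct": pct(self.sp_diff),
            "reduction_diff": self.reduction_diff,
            "sp_diff_ci": list(self.sp_diff_ci),
            "reduction_diff_ci": list(self.reduction_diff_ci),
            "n_bootstrap": self.n_bootstrap,
            "seed": self.seed,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _bootstrap_rates(
    truth: np.ndarray, screen: np.ndarray, n_boot: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """(sp, reduction) per bootstrap resample, rule held fixed."""
    n = truth.size
    sp = np.empty(n_boot)
    reduction = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        t = truth[idx]
        s = screen[idx]
        negatives = int(np.sum(~t))
        sp[b] = np.sum(~t & ~s) / negatives if negatives else np.nan
        reduction[b] = np.sum(~s) / n
    return sp, reduction


def compare_devices(
    cohort_a: Cohort,
    cohort_b: Cohort,
    se_target: float = 0.95,
    culture_config: CultureLabelConfig | None = None,
    n_bootstrap: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> DeviceComparison:
    """Optimize each device under se >= se_target and compare operating points.

    Differences are A minus B; swapping the arguments negates them.
    Bootstrap percentile intervals resample each cohort independently with
    replacement (seeded), keeping each device's chosen rule fixed.

    Raises :class:`ContractError` naming the device when the sensitivity
    floor is unachievable on its cohort.
    """
    reports = []
    screens = []
    truths = []
    for name, cohort in (("A", cohort_a), ("B", cohort_b)):
        cohort.require_nonempty()
        config = culture_config or cohort.label_config
        truth = cohort.truth_labels(config)
        try:
            rule, _ = optimize_dual_counts(
                cohort.bacteria, cohort.wbc, truth,
                criterion="se_floor", se_target=se_target,
            )
        except ContractError as exc:
            raise ContractError(f"device {name} ({cohort.samples[0].device}): {exc}") from exc
        reports.append(evaluate(cohort, rule, config, ci_level))
        screens.append(apply_rule_to_counts(cohort.bacteria, cohort.wbc, rule))
        truths.append(truth)

    report_a, report_b = reports
    sp_diff = report_a.metrics.sp - report_b.metrics.sp
    reduction_diff = report_a.metrics.reduction - report_b.metrics.reduction

    rng = np.random.default_rng(seed)
    sp_a, red_a = _bootstrap_rates(truths[0], screens[0], n_bootstrap, rng)
    sp_b, red_b = _bootstrap_rates(truths[1], screens[1], n_bootstrap, rng)
    alpha = 100.0 * (1.0 - ci_level) / 2.0
    sp_ci = tuple(np.nanpercentile(sp_a - sp_b, [alpha, 100.0 - alpha]))
    red_ci = tuple(np.percentile(red_a - red_b, [alpha, 100.0 - alpha]))
    return DeviceComparison(
        se_target=se_target,
        report_a=report_a,
        report_b=report_b,
        sp_diff=float(sp_diff),
        reduction_diff=float(reduction_diff),
        sp_diff_ci=(float(sp_ci[0]), float(sp_ci[1])),
        reduction_diff_ci=(float(red_ci[0]), float(red_ci[1])),
        n_bootstrap=n_bootstrap,
        seed=seed,
    )
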