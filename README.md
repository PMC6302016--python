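# uroscreen

Diagnostic-accuracy evaluation of automated urine-screening analysers
against urine culture.

## The problem

Urine culture is the gold standard for diagnosing urinary tract infection,
but it takes 24–48 h and most cultured plates come back negative.
Automated analysers (urine flow cytometers and flow-imaging microscopes)
report bacteria and leukocyte particle counts (/μL) in minutes, so a
clinical microbiology laboratory can *screen out* samples that are very
unlikely to grow: a sample is screen-negative — and not cultured — when
both counts fall below device-specific cut-offs. The screen is acceptable
only if it almost never discards a culture-positive sample (guidelines ask
for sensitivity above 90–95% at the significant-bacteriuria threshold of
10⁵ CFU/mL), and it is worthwhile only if it removes a substantial
fraction of the culture workload.

`uroscreen` is the analysis pipeline for that evaluation, aimed at
laboratory scientists comparing screening analysers:

- **culture labelling** — truth is positive iff growth ≥ a CFU/mL
  threshold (default 10⁵, alternate 10⁴); contaminated cultures (≥3 colony
  types) stay in the denominator as truth-negative;
- **ROC/AUC per channel** — empirical ROC with the *flag at or above*
  convention, thresholds restricted to observed machine readings, AUC by
  trapezoid (≡ the rank statistic P(X₊ > X₋) + ½P(X₊ = X₋));
- **cut-off optimization** — single-marker and combined
  *bacteria ≥ t_b OR WBC ≥ t_w* rules, optimized exhaustively over the
  product grid of observed values under Youden's J (Se + Sp − 1) or a
  sensitivity floor (maximize Sp subject to Se ≥ target, default 0.95),
  plus the full nondominated (Se, Sp) frontier;
- **operating-point metrics** — Se, Sp, PPV, NPV, accuracy, the workload
  **reduction** (TN+FN)/N, Wilson intervals, and the Bayes identities
  (e.g. PPV = Se·p / (Se·p + (1−Sp)(1−p))) that let published (Se, Sp,
  prevalence) triples be audited without per-sample data;
- **two-device comparison at matched sensitivity** — each device optimized
  independently under the same Se floor, with seeded bootstrap intervals
  on the Sp and reduction differences;
- **synthetic cohorts** — seeded class-conditional bivariate log-normal
  counts whose per-channel AUC is calibrated in closed form
  (AUC = Φ(Δμ/√(σ₋²+σ₊²))), standing in for real instrument exports.

## Worked example

```python
from uroscreen import (GeneratorConfig, generate_cohort, build_roc,
                       optimize_dual, rates_to_predictive_values, pct)

cohort = generate_cohort(GeneratorConfig(n=1220, seed=7))
truth = cohort.truth_labels()
print(f"cohort: n={len(cohort)}, culture-positive={int(truth.sum())} "
      f"({pct(truth.mean())}%)")

curve = build_roc(cohort.bacteria, truth)
print(f"bacteria channel AUC: {curve.auc:.3f}")

rule, m = optimize_dual(cohort, criterion="se_floor", se_target=0.95)
print(f"optimal rule: bacteria >= {rule.t_bac:.1f}/uL OR WBC >= {rule.t_wbc:.1f}/uL")
print(f"se={pct(m.se)}%  sp={pct(m.sp)}%  ppv={pct(m.ppv)}%  "
      f"npv={pct(m.npv)}%  reduction={pct(m.reduction)}%")

pv = rates_to_predictive_values(0.953, 0.704, 213 / 1220)
print(f"published operating point audit: ppv={pct(pv.ppv)}%  npv={pct(pv.npv)}%")
```

prints

```
cohort: n=1220, culture-positive=240 (19.7%)
bacteria channel AUC: 0.942
optimal rule: bacteria >= 132.5/uL OR WBC >= 117.9/uL
se=95.0%  sp=75.4%  ppv=48.6%  npv=98.4%  reduction=61.6%
published operating point audit: ppv=40.5%  npv=98.6%
```

Reading it: on a simulated 1220-sample cohort (19.7% culture-positive in
this draw) the bacteria channel separates the classes with AUC 0.942; the
best combined rule that keeps sensitivity at 95% flags samples with
≥ 132.5 bacteria/μL or ≥ 117.9 WBC/μL, retains 75.4% specificity, and
would spare 61.6% of cultures while keeping NPV at 98.4%. The last line
feeds a *published* operating point (Se 95.3%, Sp 70.4%, prevalence
213/1220) through Bayes' rule, recovering the predictive values that
accompany it (PPV 40.5%, NPV 98.6%).

A CLI mirrors the library:

```sh
uroscreen simulate --n 1220 --device A --seed 7 --out cohort.csv
uroscreen roc --input cohort.csv --channel bacteria
uroscreen optimize --input cohort.csv --criterion se-floor --se-target 0.95
uroscreen compare --input-a a.csv --input-b b.csv --se-target 0.95
```

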