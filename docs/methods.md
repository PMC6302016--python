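# Methods

## Ground truth and labelling

Semi-quantitative urine culture is the reference standard. A sample is
truth-positive when its growth is at or above the significant-bacteriuria
threshold — inclusive boundary, ≥ 10⁵ CFU/mL by default, with 10⁴ CFU/mL
available as a configuration knob rather than a separate code path, since
both thresholds are in routine use. Cultures growing three or more
distinct colony types are *contaminated*; they are kept in the cohort and
labelled truth-negative by default (`contaminated_is_negative=True`),
because excluding them would change every denominator. The alternative
conventions found in practice (contaminated-as-positive, or exclusion)
can be approximated by flipping that flag or filtering the cohort before
evaluation. Poor-quality specimens (inadequate volume, excess mucus,
haemolysis) are modelled only as an optional boolean `qc_excluded` column
honoured at read time; the package does not attempt to infer sample
quality from the counts.

## Decision convention and candidate thresholds

A screening rule flags a sample when a count is **at or above** its
cut-off; analyser cut-offs are "flag at or above" levels. Candidate
thresholds are the observed values of the cohort plus a +∞ sentinel (the
screen-nothing rule), never midpoints: a reported cut-off is then always a
realizable machine reading. The empirical ROC therefore has one operating
point per distinct observed value plus the sentinel, tied values collapse
to a single point, and AUC — trapezoidal area under (1−Sp, Se) — equals
the rank statistic P(X₊ > X₋) + ½ P(X₊ = X₋) exactly. This equivalence is
enforced in the tests by an independent exhaustive pair-counting oracle.

## Cut-off selection

Two criteria are implemented for both single-marker and combined rules:

* **youden** — maximize Se + Sp − 1, the conventional balance criterion;
* **se_floor(t)** — maximize Sp subject to Se ≥ t. The default target is
  0.95: screening guidelines put sensitivity above 90–95%, and a
  screen-out rule's value is the specificity (hence workload reduction)
  it retains *at* that sensitivity. "Most balanced" operating points
  reported for screening analysers sit at ≈95% sensitivity, so
  `se_floor(0.95)` is the default criterion and Youden the alternative.

Ties in the criterion are broken deterministically toward higher Se, then
the higher bacteria threshold, then the higher WBC threshold — at equal
performance the stricter rule, which flags fewer samples at the margin, is
preferred and repeated runs return the identical rule.

The combined rule is `bacteria ≥ t_b OR WBC ≥ t_w`. OR is the combiner of
record because missing a culture-positive sample is the costly error and
OR can only add flagged samples: its Se dominates both single channels and
its Sp is dominated by both (a tested invariant). An AND combiner exists
behind a flag for completeness but carries no defaults or claims.
Optimization is an exhaustive scan of the full product grid — with ~10³
distinct values per channel that is ≤ 10⁶ rule evaluations, done in one
vectorized pass from a padded 2-D cumulative count table per truth class
(flagged = N − #{b < t_b ∧ w < t_w}), so no heuristic pruning is needed.
The Pareto front over the same grid reports every nondominated (Se, Sp)
pair; the Youden and every se_floor optimum necessarily lie on it.

## Metrics

All metrics derive from the 2×2 confusion matrix at full precision:
Se = TP/(TP+FN), Sp = TN/(TN+FP), PPV = TP/(TP+FP), NPV = TN/(TN+FN),
accuracy = (TP+TN)/N, prevalence = (TP+FN)/N, and the screening-specific
**reduction = (TN+FN)/N**, the fraction of samples not sent to culture.
A zero denominator yields an explicit `None` flag, never a silent 0.
Percentages are rounded half-up to one decimal only in the report layer.
The Bayes identities (`rates_to_predictive_values`) are algebraically
identical to the confusion-matrix path at any realizable (Se, Sp,
prevalence) — a property-tested invariant — and default to the empirical
cohort prevalence, with an override for external-prevalence what-ifs.
Uncertainty on any proportion uses the Wilson score interval; the
two-device comparison adds seeded bootstrap percentile intervals (default
1000 resamples, samples drawn with replacement, each device's chosen rule
held fixed) for the Sp and reduction differences, since re-optimizing
inside every resample would mix rule-selection variability into an
interval meant to describe the chosen operating points.

Device comparison is at **matched sensitivity, not matched threshold**:
analysers report on different count scales, so each cohort is optimized
independently under the same sensitivity floor and compared on what each
retains (Sp, PPV, reduction) at that floor.

## Synthetic cohorts

No per-sample instrument data are publicly available for this kind of
evaluation, so the generator produces cohorts with the structure the
pipeline assumes. Counts are class-conditional bivariate **log-normals**:
non-negative, right-skewed, and Gaussian on the log scale, where the
single-channel AUC has the closed binormal form
AUC = Φ((μ₊ − μ₋)/√(σ₋² + σ₊²)). `calibrate_separation` inverts that
form, so a channel can be pinned to any target AUC exactly at the
population level.

Defaults (the study conditions the tests run under):

| parameter | default | rationale |
|---|---|---|
| n | 1220 | cohort size of the evaluation being emulated |
| prevalence | 213/1220 ≈ 0.1746 | its published positive fraction |
| contamination rate | 5% of negatives | no published rate; plausible for boric-acid midstream collections, freely configurable |
| log-scale σ | 1.4 (all classes/channels) | counts in urine span ~3 decades within class |
| bacteria AUC target | device A 0.943, device B 0.864 | published per-device figure-level AUCs, used as calibration inputs |
| WBC AUC target | device A 0.832, device B 0.834 | idem |
| device B `scale_shift` | −log(138/5.7) ≈ −3.19 | the ~25-fold count-scale contrast between the two analysers' published cut-offs |
| within-class log-count correlation ρ | 0.3 | bacteriuria and pyuria co-occur; mild coupling |
| anchor means | positive bacteria μ set so the population Se=0.95 cut-off sits near 100/μL; negative WBC median 10/μL | puts device A cut-offs in the empirically reported range |

Per sample: truth ~ Bernoulli(prevalence); log-counts from the class's
bivariate normal plus `scale_shift`, exponentiated; culture load drawn
uniform in log₁₀ over [5, 8] decades for positives and [0, 5) for
negatives, so truth always respects the 10⁵ CFU/mL boundary; contaminated
samples are truth-negatives with counts from an intermediate model midway
between the class means (mixed growth elevates both channels). One seed
spawns one child stream per sample index, so growing `n` extends a cohort
without reshuffling earlier samples. `scale_shift` is applied on the log
scale, which makes the equivariance exact: every downstream cut-off
scales by exp(shift) while AUC and all (Se, Sp) operating points are
unchanged — asserted in the acceptance suite.

What the generator does **not** emulate: organism-specific count
signatures (low-count false negatives from e.g. *Proteus* or *Candida*
appear in real evaluations and are not a log-normal tail), instrument
carry-over, mucus interference, detection floors/ceilings and the
quantization of real instrument exports, and any pairing of the same
physical specimen across devices (device cohorts are independent draws;
no paired per-sample analysis is supported, as the tabular dialect does
not represent cross-device pairing). Passing tests therefore show the
*pipeline* is correct under the assumed structure, not that any real
analyser attains these numbers.

## Numerical choices

* All rate arithmetic is exact integer ratios in double precision; the
  implementation and the test oracles both compute Sp as
  (TN)/(TN+FP) directly rather than 1 − FP/(TN+FP), which differs in the
  last ulp and would split criterion ties inconsistently.
* AUC ties get ½ credit, making the trapezoid and rank formulations
  identical to ~1e−16; the oracle-equivalence tests assert 1e−12.
* Cohort CSV I/O round-trips floats bit-exactly (`repr` on write,
  `float_precision="round_trip"` on read).
* Degenerate inputs: single-class truth is rejected (ROC and optimization
  undefined); an all-identical marker yields the two-point chance curve
  (AUC 0.5); the +∞ rule is a legal operating point (Se 0, reduction 1).
* A sensitivity floor ≤ 1 is always achievable (the all-flag rule has
  Se = 1), so the unachievable-floor error path concretely guards
  invalid targets.

## Problem sizes

Property and oracle suites run on hundreds of random instances of n ≤ 50,
where exhaustive double-loop oracles are exact and cheap. Calibration
recovery runs at n = 5000 per device — large enough that empirical AUC
concentrates within ±0.02 of its population target and the grid search
still evaluates its full ~25·10⁶-pair product grid in a few seconds.

## Known limitations

* Empirical AUC at n = 5000 sits slightly below the calibration target
  (~0.006 for the bacteria channel) because contaminated truth-negatives
  are drawn from the intermediate model, which thickens the negative
  class's upper tail; the effect is well inside the ±0.02 acceptance band
  and disappears at `contamination_rate=0`.
* A published workload-reduction figure of 58.3% for the cytometer-class
  device is not exactly implied by its own published Se/Sp/prevalence
  (the Bayes identity gives ≈58.9%); the discrepancy is below one
  percentage point and is asserted as such in a documentation test rather
  than resolved, since the original denominator is unstated.
* Reported cut-offs are observed machine readings, so two cohorts drawn
  from the same population yield slightly different optimal thresholds;
  operating-point rates, not thresholds, are the stable comparison
  quantities.
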