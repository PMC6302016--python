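"""OR-rule semantics, joint grid optimization and the Pareto frontier."""

import numpy as np
import pytest

from conftest import naive_dual_optimize, random_instance
from uroscreen import (
    Cohort,
    ContractError,
    DualThresholdRule,
    UrineSample,
    apply_rule,
    apply_rule_to_counts,
    best_single_cutoff,
    optimize_dual,
    optimize_dual_counts,
    pareto_front_counts,
    threshold_metrics,
)


def _sample(bac, wbc):
    return UrineSample(sample_id=f"s{bac}-{wbc}", device="A",
                       bacteria_per_uL=bac, wbc_per_uL=wbc, culture_cfu_per_mL=0.0)


class TestApplyRule:
    @pytest.mark.parametrize(
        "bac, wbc, expected",
        [
            (150.0, 0.0, True),    # bacteria channel alone fires
            (0.0, 0.0, False),     # below both cut-offs
            (0.0, 200.0, True),    # OR: WBC channel alone fires
            (138.0, 0.0, True),    # inclusive boundary
            (137.9, 119.7, False),
        ],
    )
    def test_or_semantics_at_published_cutoffs(self, bac, wbc, expected):
        rule = DualThresholdRule(t_bac=138.0, t_wbc=119.8)
        assert apply_rule(_sample(bac, wbc), rule) is expected

    def test_missing_count_is_an_error(self):
        rule = DualThresholdRule(t_bac=1.0, t_wbc=1.0)
        with pytest.raises(ContractError):
            apply_rule_to_counts([np.nan], [1.0], rule)

    def test_infinite_threshold_silences_a_channel(self):
        rule = DualThresholdRule(t_bac=np.inf, t_wbc=10.0)
        out = apply_rule_to_counts([1e9, 1.0], [5.0, 50.0], rule)
        assert out.tolist() == [False, True]

    def test_and_combiner_flags_subset_of_or(self):
        rng = np.random.default_rng(2)
        b, w, _ = random_instance(rng)
        rule_or = DualThresholdRule(t_bac=5.0, t_wbc=4.0, combiner="or")
        rule_and = DualThresholdRule(t_bac=5.0, t_wbc=4.0, combiner="and")
        s_or = apply_rule_to_counts(b, w, rule_or)
        s_and = apply_rule_to_counts(b, w, rule_and)
        assert np.all(s_or | ~s_and)


class TestOptimizeDual:
    @pytest.mark.parametrize("criterion, target", [("youden", None), ("se_floor", 0.95)])
    def test_matches_naive_double_loop(self, criterion, target):
        rng = np.random.default_rng(31)
        for _ in range(25):
            b, w, t = random_instance(rng, n_max=20)
            rule, m = optimize_dual_counts(b, w, t, criterion, se_target=target)
            tb, tw, se, sp = naive_dual_optimize(b, w, t, criterion, target)
            assert (rule.t_bac, rule.t_wbc) == (tb, tw)
            assert m.se == pytest.approx(se, abs=1e-12)
            assert m.sp == pytest.approx(sp, abs=1e-12)

    def test_uninformative_wbc_degrades_to_single_marker(self):
        rng = np.random.default_rng(4)
        b = np.round(rng.lognormal(2, 1, 200), 2)
        t = rng.random(200) < 0.3
        t[0] = True
        t[1] = False
        w = np.full(200, 7.5)  # identical in both classes: no signal
        rule, _ = optimize_dual_counts(b, w, t, criterion="youden")
        single = best_single_cutoff(b, t, "youden")
        assert rule.t_wbc == np.inf
        assert rule.t_bac == single.threshold

    def test_or_dominance_over_single_channels(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            b, w, t = random_instance(rng, n_max=40)
            tb = float(rng.choice(np.unique(b)))
            tw = float(rng.choice(np.unique(w)))
            m = threshold_metrics(b, t, tb)
            mw = threshold_metrics(w, t, tw)
            rule = DualThresholdRule(t_bac=tb, t_wbc=tw)
            screen = apply_rule_to_counts(b, w, rule)
            se = np.sum(t & screen) / t.sum()
            sp = 1 - np.sum(~t & screen) / (~t).sum()
            assert se >= max(m.se, mw.se) - 1e-12
            assert sp <= min(m.sp, mw.sp) + 1e-12

    def test_infinite_wbc_threshold_reproduces_single_marker_metrics(self):
        rng = np.random.default_rng(8)
        b, w, t = random_instance(rng)
        for th in np.r_[np.unique(b)[:5], np.inf]:
            rule = DualThresholdRule(t_bac=float(th), t_wbc=np.inf)
            screen = apply_rule_to_counts(b, w, rule)
            single = threshold_metrics(b, t, th)
            se = np.sum(t & screen) / t.sum()
            assert se == pytest.approx(single.se, abs=1e-15)

    def test_floor_achieved_on_simulated_cohort(self, cohort_a, floor_opt_a):
        rule, metrics = floor_opt_a
        assert metrics.se >= 0.95
        # the optimum dominates a sample of feasible grid pairs
        rng = np.random.default_rng(9)
        b, w, t = cohort_a.bacteria, cohort_a.wbc, cohort_a.truth_labels()
        for _ in range(30):
            cand = DualThresholdRule(
                t_bac=float(rng.choice(b)), t_wbc=float(rng.choice(w)))
            screen = apply_rule_to_counts(b, w, cand)
            se = np.sum(t & screen) / t.sum()
            sp = 1 - np.sum(~t & screen) / (~t).sum()
            if se >= 0.95:
                assert metrics.sp >= sp - 1e-12

    def test_single_class_rejected(self):
        with pytest.raises(ContractError):
            optimize_dual_counts([1, 2], [1, 2], [True, True])

    def test_cohort_interface(self, hand_cohort):
        rule, metrics = optimize_dual(hand_cohort, criterion="youden")
        tb, tw, se, sp = naive_dual_optimize(
            hand_cohort.bacteria, hand_cohort.wbc, hand_cohort.truth_labels(),
            "youden")
        assert (rule.t_bac, rule.t_wbc) == (tb, tw)
        assert (metrics.se, metrics.sp) == (se, sp)


class TestParetoFront:
    def test_separable_cohort_single_point(self):
        b = np.array([1.0, 2.0, 50.0, 60.0])
        w = np.array([1.0, 1.0, 1.0, 1.0])
        t = np.array([False, False, True, True])
        front = pareto_front_counts(b, w, t)
        assert len(front) == 1
        _, m = front.rules[0]
        assert m.se == 1.0 and m.sp == 1.0

    def test_equals_brute_force_dominance_filter(self):
        rng = np.random.default_rng(41)
        for _ in range(10):
            b, w, t = random_instance(rng, n_max=15)
            front = pareto_front_counts(b, w, t)
            got = {(round(m.se, 12), round(m.sp, 12)) for _, m in front.rules}
            # brute force over the whole grid
            points = []
            for tb in np.r_[np.unique(b), np.inf]:
                for tw in np.r_[np.unique(w), np.inf]:
                    screen = (b >= tb) | (w >= tw)
                    points.append((np.sum(t & screen) / t.sum(),
                                   1 - np.sum(~t & screen) / (~t).sum()))
            nondominated = {
                (round(se, 12), round(sp, 12))
                for se, sp in points
                if not any(se2 >= se and sp2 >= sp and (se2 > se or sp2 > sp)
                           for se2, sp2 in points)
            }
            assert got == nondominated

    def test_criterion_optima_lie_on_front(self):
        rng = np.random.default_rng(43)
        for _ in range(10):
            b, w, t = random_instance(rng, n_max=25)
            front = {(round(m.se, 12), round(m.sp, 12))
                     for _, m in pareto_front_counts(b, w, t).rules}
            _, m_y = optimize_dual_counts(b, w, t, "youden")
            assert (round(m_y.se, 12), round(m_y.sp, 12)) in front
            _, m_f = optimize_dual_counts(b, w, t, "se_floor", se_target=0.9)
            assert (round(m_f.se, 12), round(m_f.sp, 12)) in front

    def test_members_mutually_nondominated(self):
        rng = np.random.default_rng(47)
        b, w, t = random_instance(rng, n_max=30)
        rules = pareto_front_counts(b, w, t).rules
        for i, (_, mi) in enumerate(rules):
            for j, (_, mj) in enumerate(rules):
                if i != j:
                    assert not (mj.se >= mi.se and mj.sp >= mi.sp
                                and (mj.se > mi.se or mj.sp > mi.sp))

    def test_frame_export(self):
        b = np.array([1.0, 2.0, 50.0, 60.0])
        w = np.array([3.0, 1.0, 9.0, 1.0])
        t = np.array([False, False, True, True])
        frame = pareto_front_counts(b, w, t).to_frame()
        assert {"t_bac", "t_wbc", "se", "sp", "reduction"} <= set(frame.columns)
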