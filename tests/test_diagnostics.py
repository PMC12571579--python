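"""Diagnostic accuracy: ISH classification, exact CIs, treatment rules."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from her2calib import diagnostics as dg
from her2calib.consensus import LabCriterion


class TestClassifyISH:
    @pytest.mark.parametrize("ratio,expected", [
        (2.0, True),     # boundary of the amplified band
        (3.2, True),
        (1.0, False),
        (1.99, False),
    ])
    def test_threshold_at_two(self, ratio, expected):
        assert dg.classify_ish(ratio) is expected

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValueError):
            dg.classify_ish(0.0)


def _cons(rows):
    return pd.DataFrame(rows, columns=["core_id", "rounded_score"])


def _ish(rows):
    return pd.DataFrame(rows, columns=["core_id", "ish_ratio", "ish_evaluable"])


class TestTrastuzumabConfusion:
    def test_three_plus_amplified_is_tp(self):
        c = dg.trastuzumab_confusion(_cons([("c", 3.0)]), _ish([("c", 4.0, True)]))
        assert (c.tp, c.tn, c.fp, c.fn) == (1, 0, 0, 0)

    def test_low_score_amplified_is_fn(self):
        c = dg.trastuzumab_confusion(_cons([("c", 1.0)]), _ish([("c", 2.5, True)]))
        assert c.fn == 1

    def test_two_plus_resolved_by_reflex_ish(self):
        amp = dg.trastuzumab_confusion(_cons([("c", 2.0)]), _ish([("c", 2.5, True)]))
        unamp = dg.trastuzumab_confusion(_cons([("c", 2.0)]), _ish([("c", 1.2, True)]))
        assert amp.tp == 1 and unamp.tn == 1

    def test_nonevaluable_cores_excluded(self):
        c = dg.trastuzumab_confusion(_cons([("c", 3.0)]), _ish([("c", 4.0, False)]))
        assert c.total == 0

    def test_counts_match_brute_force_on_cohort(self, study):
        from her2calib.consensus import consensus_scores, select_labs
        labs = select_labs(study["labs"],
                           LabCriterion.interval(30e3, 60e3, readout="manual"))
        cons = consensus_scores(study["scores"], labs)
        counts = dg.trastuzumab_confusion(cons, study["ish"])
        # independent enumeration
        ish = study["ish"]
        ish = ish[ish["ish_evaluable"]]
        merged = cons.merge(ish, on="core_id")
        tp = tn = fp = fn = 0
        for _, row in merged.iterrows():
            amp = row["ish_ratio"] >= 2.0
            pos = row["rounded_score"] == 3.0 or (row["rounded_score"] == 2.0 and amp)
            tp += pos and amp
            fp += pos and not amp
            fn += (not pos) and amp
            tn += (not pos) and (not amp)
        assert (counts.tp, counts.tn, counts.fp, counts.fn) == (tp, tn, fp, fn)
        assert counts.total == len(merged)


class TestClopperPearson:
    @pytest.mark.parametrize("k,n,lo,hi", [
        (18, 21, 63.66, 96.95),
        (49, 49, 92.75, 100.00),
        (18, 18, 81.47, 100.00),
        (49, 52, 84.05, 98.79),
    ])
    def test_survey_interval_bounds(self, k, n, lo, hi):
        ci = dg.clopper_pearson(k, n, 0.05)
        assert round(ci[0] * 100, 2) == lo
        assert round(ci[1] * 100, 2) == hi

    def test_degenerate_endpoints(self):
        assert dg.clopper_pearson(0, 10)[0] == 0.0
        assert dg.clopper_pearson(10, 10)[1] == 1.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            dg.clopper_pearson(1, 0)
        with pytest.raises(ValueError):
            dg.clopper_pearson(5, 4)

    def test_empirical_coverage_at_least_nominal(self):
        # exact intervals are conservative: coverage >= 95% by construction
        n, p, reps = 20, 0.8, 10_000
        bounds = [dg.clopper_pearson(k, n, 0.05) for k in range(n + 1)]
        rng = np.random.default_rng(2024)
        ks = rng.binomial(n, p, reps)
        covered = sum(bounds[k][0] <= p <= bounds[k][1] for k in ks)
        assert covered / reps >= 0.95


class TestDiagnosticMetrics:
    def test_survey_point_estimates(self):
        counts = dg.ConfusionCounts(tp=18, tn=49, fp=0, fn=3)
        m = dg.diagnostic_metrics(counts)
        assert m.sensitivity == pytest.approx(18 / 21)
        assert m.specificity == pytest.approx(1.0)
        assert m.npv == pytest.approx(49 / 52)
        assert m.ppv == pytest.approx(1.0)

    def test_accuracy_formula(self):
        m = dg.diagnostic_metrics(dg.ConfusionCounts(tp=3, tn=5, fp=1, fn=1))
        assert m.accuracy == pytest.approx(0.8)

    def test_zero_denominator_reported_as_nan(self):
        m = dg.diagnostic_metrics(dg.ConfusionCounts(tp=0, tn=5, fp=0, fn=0))
        assert np.isnan(m.sensitivity) and np.isnan(m.ppv)
        assert m.specificity == 1.0

    def test_ci_brackets_each_point_estimate(self):
        m = dg.diagnostic_metrics(dg.ConfusionCounts(tp=18, tn=49, fp=0, fn=3))
        for name, point in [("sensitivity", m.sensitivity), ("npv", m.npv)]:
            lo, hi = m.ci[name]
            assert lo <= point <= hi


class TestTreatmentRule:
    def test_default_rule_matches_frozen_logic_table(self):
        # exhaustive enumeration over score x amplification product space
        rule = dg.TreatmentRule()
        expected = {
            (0.0, False): False, (0.0, True): False,
            (0.5, False): True, (0.5, True): True,
            (1.0, False): True, (1.0, True): True,
            (2.0, False): True, (2.0, True): False,   # reflex ISH excludes
            (3.0, False): False, (3.0, True): False,  # routed to Trastuzumab
        }
        for (score, amp), want in expected.items():
            assert rule.decide(score, amp) is want

    def test_no_ultralow_rule_over_standard_levels(self):
        rule = dg.TreatmentRule(include_ultralow=False)
        decisions = {s: rule.decide(s, False) for s in (0.0, 1.0, 2.0, 3.0)}
        assert decisions == {0.0: False, 1.0: True, 2.0: True, 3.0: False}

    def test_score_outside_active_set_rejected(self):
        with pytest.raises(ValueError):
            dg.TreatmentRule(include_ultralow=False).decide(0.5, False)

    def test_without_ish_two_plus_is_eligible(self):
        assert dg.TreatmentRule().decide(2.0, None) is True

    @pytest.mark.parametrize("treat_scores", [
        frozenset({1.0}), frozenset({0.5, 1.0}), frozenset({1.0, 2.0, 3.0}),
    ])
    def test_alternative_rules_match_enumeration(self, treat_scores):
        rule = dg.TreatmentRule(treat_scores=treat_scores,
                                exclude_amplified_2plus=False)
        for score, amp in itertools.product((0.0, 0.5, 1.0, 2.0, 3.0),
                                            (False, True)):
            assert rule.decide(score, amp) is (score in treat_scores)


class TestAccuracyProfile:
    def test_single_lab_gold_standard_scores_itself_perfectly(self, study):
        labs = study["labs"]
        one = labs[labs["readout"] == "image_analysis"].iloc[[0]]
        crit = LabCriterion(lambda df: df["lab_id"] == one["lab_id"].iloc[0],
                            "single lab")
        gold = dg.tdxd_gold_standard(study["scores"], labs, crit)
        prof = dg.lab_accuracy_profile(study["scores"], one, gold)
        assert prof["accuracy"].iloc[0] == 1.0

    def test_confusion_conserves_core_count(self, study):
        crit = LabCriterion.lod_above(40e3, readout="image_analysis")
        gold = dg.tdxd_gold_standard(study["scores"], study["labs"], crit)
        prof = dg.lab_accuracy_profile(study["scores"], study["labs"], gold,
                                       readout="image_analysis")
        totals = prof[["tp", "tn", "fp", "fn"]].sum(axis=1)
        assert (totals == len(gold)).all()

    def test_profile_ordered_by_lod(self, study):
        crit = LabCriterion.lod_above(40e3, readout="image_analysis")
        gold = dg.tdxd_gold_standard(study["scores"], study["labs"], crit)
        prof = dg.lab_accuracy_profile(study["scores"], study["labs"], gold,
                                       readout="image_analysis")
        assert prof["lod"].is_monotonic_increasing

    def test_matched_sensitivity_labs_are_most_accurate(self, study):
        rule = dg.TreatmentRule()
        crit = LabCriterion.lod_above(40e3, readout="image_analysis")
        gold = dg.tdxd_gold_standard(study["scores"], study["labs"], crit,
                                     rule, study["ish"])
        prof = dg.lab_accuracy_profile(study["scores"], study["labs"], gold,
                                       rule, study["ish"],
                                       readout="image_analysis")
        high = prof.loc[prof["lod"] >= 40e3, "accuracy"].mean()
        low = prof.loc[prof["lod"] < 20e3, "accuracy"].mean()
        assert high > low
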