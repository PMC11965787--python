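import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.proportion import proportion_confint

from ppgrhythm import (
    AF_ONLY,
    AF_OR_AFL,
    ConfusionTable,
    apply_exclusions,
    build_report,
    compare_proportions,
    comparison_report,
    compute_auroc,
    compute_metrics,
    confusion_from_records,
    f1_from_se_ppv,
    per_participant_agreement,
)
from ppgrhythm.evaluation import comparison_markdown


def records_frame(rows):
    defaults = {"subject_id": "X", "day": 0, "ecg_label": "SR",
                "ppg_sufficient": True, "certainty": 0.99, "pred_label": "SR",
                "p_AF": 0.01}
    return pd.DataFrame([{**defaults, **r} for r in rows])


class TestExclusions:
    def test_fixture_ledger(self):
        rows = [{} for _ in range(7)]
        rows += [{"ecg_label": "INSUFFICIENT"},
                 {"ppg_sufficient": False},
                 {"certainty": 0.85}]
        analysis, ledger = apply_exclusions(records_frame(rows), gate=0.9)
        assert len(analysis) == 7
        assert ledger == {"ecg_insufficient": 1, "ppg_insufficient": 1,
                          "low_certainty": 1, "other": 0}

    def test_priority_order_counts_each_record_once(self):
        rows = [{"ecg_label": "INSUFFICIENT", "certainty": 0.5,
                 "ppg_sufficient": False}]
        _, ledger = apply_exclusions(records_frame(rows))
        assert ledger["ecg_insufficient"] == 1
        assert sum(ledger.values()) == 1

    def test_missing_classification_with_good_quality_is_other(self):
        rows = [{"certainty": np.nan}]
        _, ledger = apply_exclusions(records_frame(rows))
        assert ledger["other"] == 1

    def test_exact_gate_value_is_accepted(self):
        analysis, ledger = apply_exclusions(
            records_frame([{"certainty": 0.9}]), gate=0.9
        )
        assert len(analysis) == 1 and ledger["low_certainty"] == 0

    @given(st.lists(
        st.fixed_dictionaries({
            "ecg_label": st.sampled_from(["SR", "AF", "AFL", "INSUFFICIENT"]),
            "ppg_sufficient": st.booleans(),
            "certainty": st.one_of(st.just(np.nan), st.floats(0.5, 1.0)),
        }), min_size=1, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_ledger_conservation(self, rows):
        analysis, ledger = apply_exclusions(records_frame(rows))
        assert sum(ledger.values()) + len(analysis) == len(rows)


class TestMetrics:
    def test_symmetric_table_hand_computation(self):
        m = compute_metrics(ConfusionTable(tp=99, fn=1, tn=99, fp=1))
        for name in ("sensitivity", "specificity", "accuracy", "ppv"):
            assert m[name].value == pytest.approx(99.0)

    def test_f1_identities_from_reported_operating_points(self):
        assert round(f1_from_se_ppv(99.7, 99.2), 1) == 99.4
        assert round(f1_from_se_ppv(99.3, 98.1), 1) == 98.7

    def test_empty_margin_reported_undefined_not_zero(self):
        m = compute_metrics(ConfusionTable(tp=0, fp=0, tn=10, fn=5))
        assert m["ppv"] is None
        assert m["specificity"] is not None

    def test_accuracy_identity_on_random_tables(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            tp, fp, tn, fn = rng.integers(1, 200, 4)
            m = compute_metrics(ConfusionTable(int(tp), int(fp), int(tn), int(fn)))
            p, n = tp + fn, tn + fp
            expect = (m["sensitivity"].value * p + m["specificity"].value * n) / (p + n)
            assert m["accuracy"].value == pytest.approx(expect)

    def test_wilson_interval_coverage_near_one(self):
        # p = 0.997, n = 5000, 1000 replicates: nominal 95% coverage
        rng = np.random.default_rng(99)
        k = rng.binomial(5000, 0.997, size=1000)
        lo, hi = proportion_confint(k, 5000, alpha=0.05, method="wilson")
        coverage = np.mean((lo <= 0.997) & (0.997 <= hi))
        assert 0.93 <= coverage <= 0.97

    def test_ci_brackets_point_estimate(self):
        m = compute_metrics(ConfusionTable(tp=500, fp=3, tn=700, fn=2))
        for v in m.values():
            assert v.ci_low <= v.value <= v.ci_high


class TestAuroc:
    def test_perfect_separation(self):
        assert compute_auroc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_pure_ties(self):
        assert compute_auroc([0.5] * 10, [1, 0] * 5) == 0.5

    def test_four_point_example(self):
        # brute force over the 4 positive-negative pairs gives 3/4
        assert compute_auroc([0.9, 0.8, 0.4, 0.3], [1, 0, 1, 0]) == 0.75

    def test_matches_brute_force_pair_counting(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            n = int(rng.integers(10, 200))
            scores = np.round(rng.random(n), 2)  # force some ties
            labels = rng.random(n) < 0.4
            if labels.all() or not labels.any():
                continue
            pos, neg = scores[labels], scores[~labels]
            wins = (pos[:, None] > neg[None, :]).sum()
            ties = (pos[:, None] == neg[None, :]).sum()
            brute = (wins + 0.5 * ties) / (len(pos) * len(neg))
            assert compute_auroc(scores, labels) == pytest.approx(brute)

    def test_single_class_undefined(self):
        with pytest.raises(ValueError):
            compute_auroc([0.1, 0.2], [1, 1])


class TestProportionComparison:
    def test_identical_proportions_give_p_one(self):
        p, chi2 = compare_proportions(10, 100, 10, 100)
        assert p == pytest.approx(1.0)
        assert chi2 == pytest.approx(0.0)

    def test_published_quality_contrast_is_significant(self):
        p, _ = compare_proportions(526, 12826, 0, 5179)
        assert p < 0.0001

    def test_balanced_table_statistic_zero(self):
        p, chi2 = compare_proportions(5, 10, 5, 10)
        assert chi2 == pytest.approx(0.0)

    def test_fisher_option(self):
        p, odds = compare_proportions(9, 10, 1, 10, method="fisher")
        assert p < 0.05

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            compare_proportions(5, 4, 0, 10)


class TestAgreement:
    def test_full_agreement_counts_all_subjects(self):
        df = records_frame([{"subject_id": f"S{i}", "ecg_label": "AF",
                             "pred_label": "AF"} for i in range(5)])
        agg = per_participant_agreement(df)
        assert agg["full_agreement"] == 5
        assert agg["at_most_one_disagreement"] == 5

    def test_single_mismatch_boundary(self):
        rows = [{"subject_id": "A", "ecg_label": "AF", "pred_label": "AF"}] * 4
        rows += [{"subject_id": "A", "ecg_label": "AF", "pred_label": "SR"}]
        agg = per_participant_agreement(records_frame(rows))
        assert agg["full_agreement"] == 0
        assert agg["at_most_one_disagreement"] == 1

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        rows = [{"subject_id": f"S{i % 4}",
                 "ecg_label": rng.choice(["SR", "AF"]),
                 "pred_label": rng.choice(["SR", "AF"])} for i in range(40)]
        df = records_frame(rows)
        a = per_participant_agreement(df)
        b = per_participant_agreement(df.sample(frac=1.0, random_state=3))
        assert a == b

    def test_afl_records_excluded_from_dichotomization(self):
        rows = [{"subject_id": "A", "ecg_label": "AFL", "pred_label": "SR"},
                {"subject_id": "A", "ecg_label": "AF", "pred_label": "AF"}]
        agg = per_participant_agreement(records_frame(rows))
        assert agg["full_agreement"] == 1


class TestReportsAndComparison:
    def make_report(self, n_pos=60, n_neg=60, errors=0, insufficient=0):
        rows = []
        for i in range(n_pos):
            wrong = i < errors
            rows.append({"subject_id": f"P{i % 7}", "ecg_label": "AF",
                         "pred_label": "SR" if wrong else "AF",
                         "p_AF": 0.2 if wrong else 0.95})
        for i in range(n_neg):
            rows.append({"subject_id": f"P{i % 7}", "ecg_label": "SR",
                         "pred_label": "SR", "p_AF": 0.05})
        for _ in range(insufficient):
            rows.append({"ppg_sufficient": False})
        return build_report(records_frame(rows), positive_definition=AF_ONLY,
                            score_column="p_AF")

    def test_report_compared_with_itself_gives_p_one(self):
        rep = self.make_report(errors=2)
        comp = comparison_report(rep, rep)
        for name in ("sensitivity", "specificity", "accuracy", "ppv", "npv"):
            assert comp[name]["p"] == pytest.approx(1.0)

    def test_comparison_rows_match_published_table_shape(self):
        rep = self.make_report(errors=1, insufficient=3)
        comp = comparison_report(rep, self.make_report())
        assert set(comp) == {"participants", "recordings",
                             "insufficient_quality", "low_certainty",
                             "sensitivity", "specificity", "accuracy",
                             "ppv", "npv"}
        text = comparison_markdown(comp)
        assert "insufficient_quality" in text

    def test_mismatched_positive_definitions_rejected(self):
        rep = self.make_report()
        other = build_report(
            records_frame([{"ecg_label": "AF", "pred_label": "AF"},
                           {"ecg_label": "SR", "pred_label": "SR"}] * 5),
            positive_definition=AF_OR_AFL,
        )
        with pytest.raises(ValueError, match="positive"):
            comparison_report(rep, other)

    def test_grouped_definition_counts_afl_as_positive(self):
        rows = [{"ecg_label": "AFL", "pred_label": "AFL"},
                {"ecg_label": "AFL", "pred_label": "AF"},
                {"ecg_label": "SR", "pred_label": "SR"}]
        ct, _ = confusion_from_records(records_frame(rows), AF_OR_AFL)
        assert (ct.tp, ct.tn, ct.fp, ct.fn) == (2, 1, 0, 0)

    def test_auroc_reported_on_analyzed_set(self):
        rep = self.make_report(errors=0)
        assert rep.auroc == 1.0
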