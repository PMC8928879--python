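"""Accuracy, f-scores, misclassified runs and night filtering."""

import numpy as np
import pytest

from stablewatch.core import BehaviorLabel, Task, vocabulary
from stablewatch.evaluation import (EvaluationReport, accuracy, compare_night,
                                    extract_misclassified_runs, f_score,
                                    f_scores, filter_valid_nights,
                                    rasterize_boris, read_boris_csv,
                                    systematic_error)
from stablewatch.postprocess import PostprocessRuleSet

from conftest import D, L, O, S, U, make_seq


def random_pair(length=200, seed=0, task=Task.TOTAL):
    rng = np.random.default_rng(seed)
    vocab = vocabulary(task)
    a = [vocab[i] for i in rng.integers(0, len(vocab), length)]
    b = [vocab[i] for i in rng.integers(0, len(vocab), length)]
    return make_seq(a, task=task), make_seq(b, task=task)


class TestAccuracy:
    def test_direct_count(self):
        pred = make_seq([S, S, L], task=Task.BINARY)
        truth = make_seq([S, L, L], task=Task.BINARY)
        assert accuracy(pred, truth) == pytest.approx(2 / 3)

    def test_identical_is_one_disjoint_is_zero(self):
        a = make_seq([S, L, O], task=Task.BINARY)
        b = make_seq([L, O, S], task=Task.BINARY)
        assert accuracy(a, a) == 1.0
        assert accuracy(a, b) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            accuracy(make_seq([S]), make_seq([S, S]))


class TestFScore:
    def test_printed_formula(self):
        # tp=2, fp=1, fn=1 for Standing -> 2 / (2 + 0.5*2) = 2/3
        pred = make_seq([S, S, S, U], task=Task.TOTAL)
        truth = make_seq([S, S, U, S], task=Task.TOTAL)
        assert f_score(pred, truth, S) == pytest.approx(2 / 3)

    def test_perfect_prediction_scores_one_for_present_classes(self):
        seq = make_seq([S, U, D, O])
        for c, v in f_scores(seq, seq).items():
            if c in set(seq.labels):
                assert v == 1.0

    def test_absent_class_reported_missing(self):
        pred = make_seq([S, S], task=Task.TOTAL)
        assert f_score(pred, pred, D) is None

    def test_sklearn_cross_check(self):
        """Independent implementation check against scikit-learn."""
        from sklearn.metrics import accuracy_score, f1_score

        pred, truth = random_pair(300, seed=9)
        y_pred = [l.value for l in pred.labels]
        y_true = [l.value for l in truth.labels]
        assert accuracy(pred, truth) == pytest.approx(
            accuracy_score(y_true, y_pred))
        labels = [c.value for c in vocabulary(Task.TOTAL)]
        sk = f1_score(y_true, y_pred, labels=labels, average=None,
                      zero_division=np.nan)
        for c, v in zip(vocabulary(Task.TOTAL), sk):
            assert f_score(pred, truth, c) == pytest.approx(v)

    def test_micro_average_equals_accuracy(self):
        """With one label per interval, micro-averaged f-score == accuracy."""
        pred, truth = random_pair(400, seed=4)
        s, t = pred.labels, truth.labels
        tp = fp = fn = 0
        for c in vocabulary(Task.TOTAL):
            tp += sum(1 for a, b in zip(s, t) if a is c and b is c)
            fp += sum(1 for a, b in zip(s, t) if a is c and b is not c)
            fn += sum(1 for a, b in zip(s, t) if a is not c and b is c)
        micro = tp / (tp + 0.5 * (fp + fn))
        assert micro == pytest.approx(accuracy(pred, truth))


class TestMisclassifiedRuns:
    def test_single_run_with_type(self):
        truth = make_seq([S, S, S, S], task=Task.BINARY)
        pred = make_seq([S, L, L, S], task=Task.BINARY)
        runs = extract_misclassified_runs(pred, truth)
        assert len(runs) == 1
        r = runs[0]
        assert (r.truth_label, r.pred_label, r.start, r.duration_s) == \
            (S, L, 1, 14)

    def test_identical_sequences_have_no_runs(self):
        seq = make_seq([S, L], task=Task.BINARY)
        assert extract_misclassified_runs(seq, seq) == []

    def test_changing_confusion_type_splits_runs(self):
        truth = make_seq([S, S], task=Task.BINARY)
        pred = make_seq([L, O], task=Task.BINARY)
        assert len(extract_misclassified_runs(pred, truth)) == 2

    def test_durations_account_for_all_errors(self):
        pred, truth = random_pair(250, seed=5)
        runs = extract_misclassified_runs(pred, truth)
        total = sum(r.duration_s for r in runs)
        assert total == pytest.approx(
            (1 - accuracy(pred, truth)) * truth.duration_s)
        assert (accuracy(pred, truth) == 1.0) == (runs == [])
        for a, b in zip(runs, runs[1:]):  # ordered, non-overlapping
            assert a.end <= b.start


class TestCompareNight:
    def test_identical_sequences_give_perfect_report(self):
        rules = PostprocessRuleSet.default(Task.BINARY)
        seq = make_seq([S] * 100 + [L] * 100, task=Task.BINARY)
        rep = compare_night(seq, seq, rules)
        assert rep.accuracy == 1.0
        assert all(v == 0 for v in rep.delta_phase_count.values())
        assert rep.misclassified_runs == []

    def test_sub_threshold_extra_phase_vanishes_under_shared_rules(self):
        rules = PostprocessRuleSet.default(Task.BINARY)
        base = [S] * 100 + [L] * 100
        with_blip = [S] * 50 + [L] * 10 + [S] * 40 + [L] * 100  # 70 s < 5 min
        rep = compare_night(make_seq(with_blip, task=Task.BINARY),
                            make_seq(base, task=Task.BINARY), rules)
        assert rep.accuracy == 1.0
        assert all(v == 0 for v in rep.delta_phase_count.values())

    def test_report_matches_independent_recount(self):
        from stablewatch.core import phase_stats
        from stablewatch.postprocess import apply_ruleset
        from stablewatch.synthetic import (NoiseModel, SyntheticProfile,
                                           corrupt_prediction,
                                           sample_night_sequence)
        from stablewatch.core import map_total_to_binary

        rules = PostprocessRuleSet.default(Task.BINARY)
        noise = NoiseModel.flicker(Task.BINARY, flip_p=0.02,
                                   burst_rate_per_h=2.0,
                                   burst_length_max_intervals=7)
        profile = SyntheticProfile.for_demographic("adult_female",
                                                   night_length_h=2.0)
        for seed in range(5):
            truth = map_total_to_binary(sample_night_sequence(profile, seed))
            pred = corrupt_prediction(truth, noise, 100 + seed)
            rep = compare_night(pred, truth, rules)
            pp, tt = apply_ruleset(pred, rules), apply_ruleset(truth, rules)
            sp, st_ = phase_stats(pp), phase_stats(tt)
            for c in vocabulary(Task.BINARY):
                assert rep.delta_phase_count[c] == \
                    sp.phase_count[c] - st_.phase_count[c]
                assert rep.delta_percentage[c] == pytest.approx(
                    sp.percentage[c] - st_.percentage[c])
            assert rep.accuracy == pytest.approx(accuracy(pp, tt))

    def test_systematic_error_compares_against_raw_truth(self):
        rules = PostprocessRuleSet.default(Task.BINARY)
        labels = [S] * 100 + [L] * 10 + [S] * 100  # short real Lying bout
        rep = systematic_error(make_seq(labels, task=Task.BINARY), rules)
        assert rep.delta_phase_count[L] == -1  # the rules dismissed it
        assert rep.accuracy < 1.0


class TestNightFiltering:
    def _report(self, pred_frac, truth_frac, night="n"):
        return EvaluationReport(
            night_id=night, individual_id="a", task=Task.BINARY,
            accuracy=1.0, f_score={}, delta_phase_count={},
            delta_median_phase_s={}, delta_percentage={},
            misclassified_runs=[], pred_out_fraction=pred_frac,
            truth_out_fraction=truth_frac)

    @pytest.mark.parametrize("pred, truth, kept", [
        (0.25, 0.05, False),  # prediction 25% Out -> dismissed
        (0.10, 0.10, True),
        (0.20, 0.00, False),  # exactly 20%: "at least" is inclusive
        (0.00, 0.20, False),
        (0.199, 0.199, True),
    ])
    def test_dismissal_rule(self, pred, truth, kept):
        retained = filter_valid_nights([self._report(pred, truth)])
        assert (len(retained) == 1) is kept


class TestBorisIngestion:
    def test_rasterize_midpoint_rule(self, tmp_path):
        p = tmp_path / "annot.csv"
        p.write_text(
            "subject,behavior,start_s,stop_s\n"
            "a,standing,0,10\n"
            "a,lhu,10,25\n"
            "b,lhd,0,25\n"
        )
        df = read_boris_csv(p)
        seq = rasterize_boris(df, "a", "n1", n_intervals=5)
        # midpoints 3.5, 10.5, 17.5, 24.5, 31.5
        assert list(seq.labels) == [S, U, U, U, O]

    def test_missing_columns_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("subject,start\na,0\n")
        with pytest.raises(ValueError):
            read_boris_csv(p)
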