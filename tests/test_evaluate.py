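"""Cross-validation plan, fold execution, and model comparison."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from silentspeech.evaluate import (
    compare_models,
    cross_validate,
    make_cv_plan,
    run_cv,
)


def balanced_labels(n_per_class, classes="MAD"):
    return np.repeat(list(classes), n_per_class)


@dataclass
class OracleTrainer:
    """Predicts via a fixed mapping; optionally corrupts chosen ids."""

    truth: dict
    wrong_ids: tuple = ()
    tag: str = "oracle"
    seen_splits: list = None

    def fit(self, x_tr, y_tr, x_val, y_val, seed):
        if self.seen_splits is not None:
            self.seen_splits.append((x_tr.copy(), x_val.copy()))
        outer = self

        class Clf:
            def predict(self, xs):
                labels = []
                for row in xs:
                    key = int(row.ravel()[0])
                    lab = outer.truth[key]
                    if key in outer.wrong_ids:
                        lab = {"M": "A", "A": "D", "D": "M"}[lab]
                    labels.append(lab)
                return np.array(labels), np.zeros((len(xs), 3))

        return Clf()


@dataclass
class ConstantTrainer:
    label: str = "M"
    tag: str = "majority"

    def fit(self, x_tr, y_tr, x_val, y_val, seed):
        lab = self.label

        class Clf:
            def predict(self, xs):
                return np.full(len(xs), lab), np.zeros((len(xs), 3))

        return Clf()


def indexed_dataset(n_per_class=20):
    y = balanced_labels(n_per_class)
    n = len(y)
    x = np.arange(n, dtype=np.float64).reshape(n, 1, 1) * np.ones((n, 1, 4))
    ids = np.array([f"id{i}" for i in range(n)])
    return x, y, ids


class TestMakeCVPlan:
    def test_60_samples_give_10_folds_of_6_with_full_coverage(self):
        plan = make_cv_plan(60, 0.10, 10, labels=balanced_labels(20), seed=0)
        assert len(plan.folds) == 10
        assert all(len(f) == 6 for f in plan.folds)
        plan.validate_coverage()
        assert plan.reused == []  # 60 divides evenly, no reuse needed

    def test_stratification_two_per_class_per_fold(self):
        y = balanced_labels(20)
        plan = make_cv_plan(60, 0.10, 10, labels=y, seed=1)
        for fold in plan.folds:
            labs = list(y[fold])
            assert {l: labs.count(l) for l in "MAD"} == {"M": 2, "A": 2, "D": 2}

    def test_30_samples_folds_of_3(self):
        plan = make_cv_plan(30, 0.10, 10, labels=balanced_labels(10), seed=0)
        assert all(len(f) == 3 for f in plan.folds)
        plan.validate_coverage()

    def test_insufficient_iterations_rejected(self):
        with pytest.raises(ValueError, match="cannot cover"):
            make_cv_plan(60, 0.10, 5)

    def test_empty_fold_rejected(self):
        with pytest.raises(ValueError, match="empty fold"):
            make_cv_plan(5, 0.10, 10)

    def test_one_short_class_reuses_first_sample_in_first_and_last_fold(self):
        # 19 M samples where 2 x 10 seats exist: one sample is reused
        y = np.concatenate([balanced_labels(19, "M"), balanced_labels(20, "A"),
                            balanced_labels(20, "D")])
        plan = make_cv_plan(59, 6 / 59, 10, labels=y, seed=3)
        plan.validate_coverage()
        assert len(plan.reused) == 1
        idx, folds = plan.reused[0]
        assert y[idx] == "M"
        assert folds == [0, 9]  # first and last iteration

    def test_unstratified_plan_covers_everything(self):
        plan = make_cv_plan(40, 0.10, 10, seed=0)
        plan.validate_coverage()


class TestRunCV:
    def test_perfect_oracle_scores_100(self):
        x, y, ids = indexed_dataset()
        truth = {i: y[i] for i in range(len(y))}
        plan = make_cv_plan(60, 0.10, 10, labels=y, seed=0)
        report = run_cv(x, y, ids, OracleTrainer(truth), plan)
        assert report.pooled_accuracy == 1.0
        assert np.all(report.confusion == np.diag(report.confusion.diagonal()))
        assert report.misclassified_ids == []

    def test_majority_dummy_on_balanced_data_scores_one_third(self):
        x, y, ids = indexed_dataset()
        plan = make_cv_plan(60, 0.10, 10, labels=y, seed=0)
        report = run_cv(x, y, ids, ConstantTrainer("M"), plan)
        assert report.pooled_accuracy == pytest.approx(1 / 3, abs=1e-12)

    def test_three_misclassified_of_60_gives_95_percent(self):
        x, y, ids = indexed_dataset()
        truth = {i: y[i] for i in range(len(y))}
        # two D (indices 40, 41) and one M (index 0) misclassified
        trainer = OracleTrainer(truth, wrong_ids=(0, 40, 41))
        plan = make_cv_plan(60, 0.10, 10, labels=y, seed=0)
        report = run_cv(x, y, ids, trainer, plan)
        assert report.pooled_accuracy == pytest.approx(0.95)
        assert sorted(report.misclassified_ids) == ["id0", "id40", "id41"]

    def test_no_fold_leaks_validation_into_training(self):
        x, y, ids = indexed_dataset()
        truth = {i: y[i] for i in range(len(y))}
        trainer = OracleTrainer(truth, seen_splits=[])
        plan = make_cv_plan(60, 0.10, 10, labels=y, seed=2)
        run_cv(x, y, ids, trainer, plan)
        for x_tr, x_val in trainer.seen_splits:
            tr_keys = {int(r.ravel()[0]) for r in x_tr}
            val_keys = {int(r.ravel()[0]) for r in x_val}
            assert tr_keys.isdisjoint(val_keys)

    def test_plan_size_mismatch_rejected(self):
        x, y, ids = indexed_dataset()
        plan = make_cv_plan(30, 0.10, 10, seed=0)
        with pytest.raises(ValueError, match="plan"):
            run_cv(x, y, ids, ConstantTrainer(), plan)


class TestCrossValidate:
    def test_reports_best_and_dispersion(self):
        x, y, ids = indexed_dataset()
        truth = {i: y[i] for i in range(len(y))}
        best, reports = cross_validate(x, y, ids, OracleTrainer(truth),
                                       repetitions=3, seed=0)
        assert len(reports) == 3
        assert best.pooled_accuracy == 1.0
        assert best.meta["mean_accuracy"] == 1.0
        assert best.meta["sd_accuracy"] == 0.0

    def test_pure_function_of_seed(self):
        x, y, ids = indexed_dataset()
        truth = {i: y[i] for i in range(len(y))}
        trainer = OracleTrainer(truth, wrong_ids=(3, 17, 30))
        b1, _ = cross_validate(x, y, ids, trainer, repetitions=2, seed=5)
        b2, _ = cross_validate(x, y, ids, trainer, repetitions=2, seed=5)
        assert b1.pooled_accuracy == b2.pooled_accuracy
        assert b1.misclassified_ids == b2.misclassified_ids


class TestCompareModels:
    def _report(self, tag, acc):
        from silentspeech.evaluate import CVReport
        conf = np.diag([int(round(acc * 60))]) if acc == 1.0 else np.array(
            [[int(round(acc * 60)), 60 - int(round(acc * 60))], [0, 0]])
        return CVReport(model_tag=tag, class_order=("M", "A"),
                        fold_accuracies=[acc], confusion=conf,
                        misclassified_ids=[])

    def test_rows_preserve_given_order(self):
        reps = [self._report("lstm", 0.68), self._report("fewshot", 0.85),
                self._report("fewshot+aug", 0.95)]
        table = compare_models(reps)
        assert list(table["model"]) == ["lstm", "fewshot", "fewshot+aug"]

    def test_single_report(self):
        table = compare_models([self._report("lstm", 0.5)])
        assert len(table) == 1

    def test_duplicate_tags_suffixed(self):
        table = compare_models([self._report("lstm", 0.5),
                                self._report("lstm", 0.6)])
        assert list(table["model"]) == ["lstm", "lstm-2"]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compare_models([])


class TestSubjectHoldout:
    def test_splits_are_complementary(self):
        from silentspeech.evaluate import subject_holdout_split

        subjects = np.repeat(["S1", "S2"], 6)
        splits = subject_holdout_split(subjects)
        assert set(splits) == {"S1", "S2"}
        tr, te = splits["S1"]
        assert sorted(np.concatenate([tr, te])) == list(range(12))
        assert set(subjects[te]) == {"S1"}
        assert set(subjects[tr]) == {"S2"}

    def test_single_subject_rejected(self):
        from silentspeech.evaluate import subject_holdout_split

        with pytest.raises(ValueError, match="two subjects"):
            subject_holdout_split(["S1", "S1"])
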