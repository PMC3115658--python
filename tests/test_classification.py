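"""Majority voting, classifiers, metrics, and cross-validation."""

import numpy as np
import pandas as pd
import pytest

from cracklekit.classification_eval import (EvalMetrics, classify_breath,
                                            cross_validate,
                                            train_crackle_classifier, vote)


class TestVote:
    def test_worked_example_breath_majority(self):
        # 6 breaths: 3 IPF, 2 CHF, 1 PN -> patient classified IPF
        tally = vote(["IPF", "IPF", "IPF", "CHF", "CHF", "PN"], unit="patient")
        assert tally.winner == "IPF"
        assert not tally.tie_flag
        assert tally.votes == {"IPF": 3, "CHF": 2, "PN": 1}

    def test_single_member(self):
        assert vote(["CHF"]).winner == "CHF"

    def test_unanimous_any_size(self):
        for n in (1, 2, 5, 17):
            assert vote(["PN"] * n).winner == "PN"

    def test_tie_broken_by_summed_score(self):
        tally = vote(["IPF", "CHF"], scores=[0.9, 0.6])
        assert tally.winner == "IPF"
        assert tally.tie_flag

    def test_tie_broken_by_priority_without_scores(self):
        tally = vote(["IPF", "CHF"], priority=("CHF", "IPF"))
        assert tally.winner == "CHF"
        assert tally.tie_flag

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            vote([])


class TestMetrics:
    def test_confusion_arithmetic(self):
        m = EvalMetrics(tp=9, fn=1, tn=8, fp=2)
        assert m.sensitivity == pytest.approx(0.9)
        assert m.specificity == pytest.approx(0.8)
        assert m.accuracy == pytest.approx(0.85)

    def test_from_predictions_positive_class(self):
        y = ["IPF", "IPF", "CHF", "CHF"]
        p = ["IPF", "CHF", "CHF", "IPF"]
        m = EvalMetrics.from_predictions(y, p, positive="IPF")
        assert (m.tp, m.fn, m.tn, m.fp) == (1, 1, 1, 1)


class TestClassifier:
    def test_separable_toy_set_trains_perfectly(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.1, (30, 3)),
                       rng.normal(5, 0.1, (30, 3))])
        y = np.array(["A"] * 30 + ["B"] * 30)
        for kind in ("svm", "nn"):
            model = train_crackle_classifier(X, y, kind=kind, seed=1)
            assert (model.predict(X) == y).all()

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        with pytest.raises(ValueError, match="both classes"):
            train_crackle_classifier(X, np.array(["A"] * 10))

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(80, 4))
        y = np.where(X[:, 0] + rng.normal(0, 1, 80) > 0, "A", "B")
        m1 = train_crackle_classifier(X, y, kind="nn", seed=7)
        m2 = train_crackle_classifier(X, y, kind="nn", seed=7)
        Xt = rng.normal(size=(40, 4))
        assert np.array_equal(m1.predict(Xt), m2.predict(Xt))


class TestClassifyBreath:
    def test_unanimous_crackle_only(self):
        assert classify_breath(["IPF"] * 5, mode="crackle_only") == "IPF"

    def test_aggregate_mode_requires_model(self):
        with pytest.raises(ValueError, match="breath model"):
            classify_breath(["IPF"], mode="crackle_plus_aggregate")


def _synthetic_crackle_table(rng, n_patients=12, n_breaths=3, sep=2.0):
    """Feature table with patient-level clustering and a group shift."""
    rows = []
    for g, group in enumerate(("IPF", "CHF")):
        for p in range(n_patients):
            pid = f"{group}-{p}"
            center = rng.normal(g * sep, 1.0, size=3)
            for b in range(n_breaths):
                for _ in range(rng.integers(3, 8)):
                    f = center + rng.normal(0, 1.0, size=3)
                    rows.append({"patient": pid, "group": group, "breath": b,
                                 "f0": f[0], "f1": f[1], "f2": f[2]})
    return pd.DataFrame(rows)


class TestCrossValidate:
    def test_oracle_features_reach_perfect_metrics(self):
        rng = np.random.default_rng(0)
        df = _synthetic_crackle_table(rng, sep=50.0)
        res = cross_validate(df, task="IPF_vs_CHF", k=5, seed=1, kind="svm",
                             feature_columns=["f0", "f1", "f2"])
        for level in ("crackle", "breath", "patient"):
            m = res.metrics[level]
            assert m.sensitivity == m.specificity == m.accuracy == 1.0

    def test_no_patient_spans_folds(self):
        rng = np.random.default_rng(1)
        df = _synthetic_crackle_table(rng)
        res = cross_validate(df, task="IPF_vs_CHF", k=5, seed=2, kind="svm",
                             feature_columns=["f0", "f1", "f2"])
        pred = res.crackle_predictions
        fold_seen = {}
        for pid in pred["patient"].unique():
            fold_seen[pid] = res.fold_of_patient[pid]
        # every patient belongs to exactly one fold and all its crackles
        # were predicted exactly once
        counts = pred.groupby("patient").size()
        truth = df.groupby("patient").size()
        assert counts.sort_index().equals(truth.sort_index())

    def test_permuted_labels_give_chance_accuracy(self):
        """Null calibration: shuffling patient labels yields ~50% accuracy
        at every voting level (within Monte-Carlo error of the patient
        count)."""
        rng = np.random.default_rng(3)
        df = _synthetic_crackle_table(rng, n_patients=14, sep=3.0)
        patients = df[["patient"]].drop_duplicates()
        perm = rng.permutation(
            df.drop_duplicates("patient").set_index("patient")["group"].values)
        mapping = dict(zip(patients["patient"], perm))
        null = df.assign(group=df["patient"].map(mapping))
        res = cross_validate(null, task="IPF_vs_CHF", k=5, seed=4, kind="svm",
                             feature_columns=["f0", "f1", "f2"])
        n_pat = patients.shape[0]
        band = 3 * np.sqrt(0.25 / n_pat)
        for level in ("breath", "patient"):
            assert abs(res.metrics[level].accuracy - 0.5) < band + 0.05

    def test_fold_reduction_warning(self):
        rng = np.random.default_rng(5)
        df = _synthetic_crackle_table(rng, n_patients=3)
        with pytest.warns(UserWarning, match="reducing folds"):
            cross_validate(df, task="IPF_vs_CHF", k=5, seed=0, kind="svm",
                           feature_columns=["f0", "f1", "f2"])

    def test_unknown_task_rejected(self):
        with pytest.raises(ValueError, match="task"):
            cross_validate(pd.DataFrame(), task="CHF_vs_PN")

    def test_aggregate_mode_requires_breaths_table(self):
        rng = np.random.default_rng(6)
        df = _synthetic_crackle_table(rng)
        with pytest.raises(ValueError, match="breaths"):
            cross_validate(df, task="IPF_vs_CHF",
                           mode="crackle_plus_aggregate")

    def test_zero_crackle_breaths_excluded_and_counted(self):
        rng = np.random.default_rng(7)
        df = _synthetic_crackle_table(rng, n_patients=6)
        breaths = df[["patient", "group", "breath"]].drop_duplicates()
        extra = pd.DataFrame([{"patient": "IPF-0", "group": "IPF",
                               "breath": 99}])
        breaths = pd.concat([breaths, extra], ignore_index=True)
        for c in ("f0",):
            breaths[c] = 0.0
        res = cross_validate(df, task="IPF_vs_CHF", k=3, seed=0, kind="svm",
                             feature_columns=["f0", "f1", "f2"],
                             breaths=breaths)
        assert res.zero_crackle_breaths == 1
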