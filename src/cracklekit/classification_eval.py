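"""Crackle-level classification with breath- and patient-level majority
voting, evaluated by patient-stratified k-fold cross-validation.

Two binary tasks are evaluated (IPF vs CHF and IPF vs PN, with IPF as the
positive class).  A per-crackle classifier — an RBF-kernel maximum-margin
classifier (``svm``) or a single-hidden-layer backpropagation network
(``nn``) — is trained on the individual crackle feature vectors,
standardized on training statistics only.  Held-out crackle predictions are
then combined upward: majority voting over the crackles of a breath yields
the breath label, and majority voting over a patient's breaths yields the
patient label.  In ``crackle_plus_aggregate`` mode a second-stage breath
classifier consumes the crackle vote fractions concatenated with the
per-breath aggregate feature vector.

Folds are split at the patient level, stratified by class, so that no
patient's crackles appear in both training and validation — crackles of one
patient are correlated and splitting them would inflate accuracy.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .crackle_features import FEATURE_COLUMNS

__all__ = [
    "VoteTally",
    "EvalMetrics",
    "CVResult",
    "TASKS",
    "train_crackle_classifier",
    "vote",
    "classify_breath",
    "cross_validate",
]

TASKS = {
    "IPF_VS_CHF": ("IPF", "CHF"),
    "IPF_VS_PN": ("IPF", "PN"),
}


def _task_classes(task: str) -> tuple[str, str]:
    key = task.replace("-", "_").upper()
    if key not in TASKS:
        raise ValueError(f"unknown task {task!r}; known: {sorted(TASKS)}")
    return TASKS[key]


@dataclass
class VoteTally:
    unit: str
    votes: dict[str, int]
    winner: str
    tie_flag: bool


@dataclass(frozen=True)
class EvalMetrics:
    """Sensitivity/specificity/accuracy with IPF as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else float("nan")

    @property
    def accuracy(self) -> float:
        total = self.tp + self.fp + self.tn + self.fn
        return (self.tp + self.tn) / total if total else float("nan")

    @classmethod
    def from_predictions(cls, y_true, y_pred, positive: str) -> "EvalMetrics":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        pos_t = y_true == positive
        pos_p = y_pred == positive
        return cls(
            tp=int(np.sum(pos_t & pos_p)),
            fp=int(np.sum(~pos_t & pos_p)),
            tn=int(np.sum(~pos_t & ~pos_p)),
            fn=int(np.sum(pos_t & ~pos_p)),
        )

    def as_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
        }


def train_crackle_classifier(
    train_features: np.ndarray,
    labels: np.ndarray,
    kind: str = "svm",
    seed: int = 0,
    C: float = 1.0,
) -> Pipeline:
    """Fit a binary per-crackle classifier (standardization + model).

    ``kind`` is ``svm`` (RBF kernel) or ``nn`` (one hidden layer of 16
    units, backpropagation).  Deterministic given ``seed``.  A single-class
    training set is rejected.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("training data must contain both classes")
    seed = int(seed) % (2**31)
    if kind == "svm":
        model = SVC(kernel="rbf", C=C, gamma="scale", random_state=seed)
    elif kind == "nn":
        model = MLPClassifier(hidden_layer_sizes=(16,), max_iter=500,
                              random_state=seed)
    elif kind == "logistic":
        # ridge-regularized linear stage, used for breath-level fusion
        model = LogisticRegression(C=C, max_iter=1000, random_state=seed)
    else:
        raise ValueError(f"kind must be 'svm' or 'nn', got {kind!r}")
    pipe = Pipeline([("scale", StandardScaler()), ("model", model)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MLP convergence warnings on tiny sets
        pipe.fit(np.asarray(train_features, dtype=float), labels)
    return pipe


def _positive_scores(model: Pipeline, X: np.ndarray, positive: str) -> np.ndarray:
    """Signed score toward the positive class for each row."""
    clf = model.named_steps["model"]
    classes = list(clf.classes_)
    if hasattr(clf, "predict_proba"):
        proba = model.predict_proba(X)
        return proba[:, classes.index(positive)] - 0.5
    d = model.decision_function(X)
    return d if classes[1] == positive else -d


def vote(
    member_labels,
    scores=None,
    priority: tuple[str, ...] | None = None,
    unit: str = "unit",
) -> VoteTally:
    """Majority vote over constituent units.

    The winner is the modal label; ties are broken by the larger summed
    score, then by the configured class priority (first match wins).  The
    tie flag records whether the raw counts were tied.
    """
    labels = list(member_labels)
    if not labels:
        raise ValueError("cannot vote over an empty member list")
    counts = Counter(labels)
    top = max(counts.values())
    leaders = sorted(lab for lab, c in counts.items() if c == top)
    tie = len(leaders) > 1
    if not tie:
        return VoteTally(unit=unit, votes=dict(counts), winner=leaders[0],
                         tie_flag=False)
    if scores is not None:
        scores = list(scores)
        sums = {lab: 0.0 for lab in leaders}
        for lab, s in zip(labels, scores):
            if lab in sums:
                sums[lab] += abs(float(s))
        best = max(sums.values())
        leaders = sorted(lab for lab, s in sums.items() if abs(s - best) < 1e-12)
    if len(leaders) > 1 and priority:
        for lab in priority:
            if lab in leaders:
                leaders = [lab]
                break
    return VoteTally(unit=unit, votes=dict(counts), winner=leaders[0],
                     tie_flag=tie)


def _breath_vector(labels, s_pos, agg_vector, positive: str) -> np.ndarray:
    labels = np.asarray(labels)
    frac_pos = float(np.mean(labels == positive))
    mean_s = float(np.mean(s_pos)) if s_pos is not None and len(s_pos) else 0.0
    agg = np.asarray(agg_vector, dtype=float) if agg_vector is not None else np.zeros(0)
    return np.concatenate([[frac_pos, mean_s], agg])


def classify_breath(
    crackle_labels,
    scores=None,
    aggregate=None,
    mode: str = "crackle_only",
    model_b: Pipeline | None = None,
    positive: str = "IPF",
    priority: tuple[str, ...] | None = None,
) -> str:
    """Classify one breath from its crackles.

    ``crackle_only`` votes over the per-crackle labels; in
    ``crackle_plus_aggregate`` a trained breath-level model is applied to
    the vote fractions concatenated with the aggregate feature vector.
    """
    if mode == "crackle_only":
        return vote(crackle_labels, scores=scores, priority=priority,
                    unit="breath").winner
    if mode == "crackle_plus_aggregate":
        if model_b is None:
            raise ValueError("aggregate mode requires a trained breath model")
        x = _breath_vector(crackle_labels, scores, aggregate, positive)
        return str(model_b.predict(x[None, :])[0])
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class CVResult:
    task: str
    kind: str
    mode: str
    k: int
    metrics: dict[str, EvalMetrics]
    crackle_predictions: pd.DataFrame
    breath_predictions: pd.DataFrame
    patient_predictions: pd.DataFrame
    fold_of_patient: dict[str, int]
    zero_crackle_breaths: int = 0
    excluded_patients: int = 0


def _patient_folds(patients: pd.DataFrame, k: int, seed: int
                   ) -> tuple[dict[str, int], int]:
    """Stratified patient-level fold assignment; reduces k with a warning if
    a class has fewer patients than folds."""
    rng = np.random.default_rng(seed)
    smallest = patients.groupby("group").size().min()
    k_eff = int(min(k, smallest))
    if k_eff < k:
        warnings.warn(f"reducing folds from {k} to {k_eff}: smallest class has "
                      f"{smallest} patients")
    if k_eff < 2:
        raise ValueError("need at least 2 folds (>= 2 patients per class)")
    fold_of: dict[str, int] = {}
    for _, grp in patients.groupby("group"):
        ids = list(grp["patient"])
        rng.shuffle(ids)
        for i, pid in enumerate(ids):
            fold_of[pid] = i % k_eff
    return fold_of, k_eff


def cross_validate(
    crackles: pd.DataFrame,
    task: str = "IPF_vs_CHF",
    k: int = 5,
    seed: int = 0,
    kind: str = "svm",
    mode: str = "crackle_only",
    breaths: pd.DataFrame | None = None,
    feature_columns: list[str] | None = None,
    max_train_crackles: int = 4000,
) -> CVResult:
    """Patient-stratified k-fold cross-validation of the voting hierarchy.

    Parameters
    ----------
    crackles
        One row per crackle with ``patient``, ``group``, ``breath`` and the
        individual crackle feature columns.
    task
        ``IPF_vs_CHF`` or ``IPF_vs_PN``; the first class is positive.
    breaths
        One row per breath with ``patient``, ``breath`` and the aggregate
        feature columns; required for ``crackle_plus_aggregate`` mode and
        used to count breaths with zero detected crackles (excluded from
        voting).
    max_train_crackles
        Training crackles are subsampled (seeded) beyond this size to bound
        the cost of the kernel fit.

    Returns pooled held-out metrics at the crackle, breath, and patient
    level.
    """
    positive, negative = _task_classes(task)
    if mode == "crackle_plus_aggregate" and breaths is None:
        raise ValueError("aggregate mode requires the breaths table")
    feat_cols = feature_columns or [c for c in FEATURE_COLUMNS
                                    if c in crackles.columns]
    df = crackles[crackles["group"].isin((positive, negative))].reset_index(drop=True)
    patients = df[["patient", "group"]].drop_duplicates()
    fold_of, k_eff = _patient_folds(patients, k, seed)
    rng = np.random.default_rng(seed + 1)
    priority = (positive, negative)

    agg_cols: list[str] = []
    breaths_task = None
    if breaths is not None:
        breaths_task = breaths[breaths["group"].isin((positive, negative))]
        agg_cols = [c for c in breaths.columns
                    if c not in ("patient", "group", "breath")]

    crackle_rows, breath_rows, patient_rows = [], [], []
    for fold in range(k_eff):
        test_patients = {p for p, f in fold_of.items() if f == fold}
        train = df[~df["patient"].isin(test_patients)]
        test = df[df["patient"].isin(test_patients)]
        if test.empty:
            continue
        if len(train) > max_train_crackles:
            take = rng.choice(len(train), size=max_train_crackles, replace=False)
            train = train.iloc[np.sort(take)]
        model = train_crackle_classifier(
            train[feat_cols].to_numpy(float), train["group"].to_numpy(),
            kind=kind, seed=seed + 17 * fold)
        X_test = test[feat_cols].to_numpy(float)
        pred = model.predict(X_test)
        s_pos = _positive_scores(model, X_test, positive)

        test = test.assign(pred=pred, s_pos=s_pos)
        crackle_rows.append(test[["patient", "group", "breath", "pred", "s_pos"]])

        model_b = None
        if mode == "crackle_plus_aggregate":
            # stack the breath stage on cross-fitted vote fractions: the
            # final crackle model's in-sample votes are near-perfect and
            # would not resemble the held-out vote distribution
            tr = df[~df["patient"].isin(test_patients)].copy()
            tr_patients = tr[["patient", "group"]].drop_duplicates()
            sub_fold, n_sub = _patient_folds(tr_patients, 3, seed + 7 * fold)
            tr["pred"] = ""
            tr["s_pos"] = 0.0
            for sub in range(n_sub):
                sub_test = {p for p, f in sub_fold.items() if f == sub}
                sub_tr = tr[~tr["patient"].isin(sub_test)]
                if len(sub_tr) > max_train_crackles:
                    take = rng.choice(len(sub_tr), size=max_train_crackles,
                                      replace=False)
                    sub_tr = sub_tr.iloc[np.sort(take)]
                m_sub = train_crackle_classifier(
                    sub_tr[feat_cols].to_numpy(float),
                    sub_tr["group"].to_numpy(),
                    kind=kind, seed=seed + 17 * fold + sub)
                mask = tr["patient"].isin(sub_test)
                X_sub = tr.loc[mask, feat_cols].to_numpy(float)
                tr.loc[mask, "pred"] = m_sub.predict(X_sub)
                tr.loc[mask, "s_pos"] = _positive_scores(m_sub, X_sub, positive)
            bx, by = [], []
            for (pid, bid), g in tr.groupby(["patient", "breath"]):
                agg_row = breaths_task[(breaths_task["patient"] == pid)
                                       & (breaths_task["breath"] == bid)]
                agg_vec = (agg_row[agg_cols].iloc[0].to_numpy(float)
                           if len(agg_row) else np.zeros(len(agg_cols)))
                bx.append(_breath_vector(g["pred"], g["s_pos"], agg_vec, positive))
                by.append(g["group"].iloc[0])
            # linear fusion stage: with few training breaths a ridge
            # logistic model weights the (dominant) vote fraction reliably
            # and lets the aggregates refine borderline votes
            model_b = train_crackle_classifier(np.stack(bx), np.asarray(by),
                                               kind="logistic",
                                               seed=seed + 31 * fold)

        for (pid, bid), g in test.groupby(["patient", "breath"]):
            if mode == "crackle_plus_aggregate":
                agg_row = breaths_task[(breaths_task["patient"] == pid)
                                       & (breaths_task["breath"] == bid)]
                agg_vec = (agg_row[agg_cols].iloc[0].to_numpy(float)
                           if len(agg_row) else np.zeros(len(agg_cols)))
                lab = classify_breath(g["pred"], g["s_pos"], agg_vec,
                                      mode=mode, model_b=model_b,
                                      positive=positive, priority=priority)
            else:
                lab = classify_breath(g["pred"], g["s_pos"], mode="crackle_only",
                                      positive=positive, priority=priority)
            breath_rows.append({"patient": pid, "breath": bid,
                                "group": g["group"].iloc[0], "pred": lab})

    crackle_pred = pd.concat(crackle_rows, ignore_index=True)
    breath_pred = pd.DataFrame(breath_rows)
    patient_rows = []
    for pid, g in breath_pred.groupby("patient"):
        tally = vote(g["pred"], priority=priority, unit="patient")
        patient_rows.append({"patient": pid, "group": g["group"].iloc[0],
                             "pred": tally.winner, "tie": tally.tie_flag})
    patient_pred = pd.DataFrame(patient_rows)

    zero_breaths = 0
    if breaths_task is not None:
        voted = set(zip(breath_pred["patient"], breath_pred["breath"]))
        zero_breaths = sum(
            1 for _, r in breaths_task.iterrows()
            if (r["patient"], r["breath"]) not in voted)
    excluded = len(patients) - patient_pred["patient"].nunique()

    metrics = {
        "crackle": EvalMetrics.from_predictions(
            crackle_pred["group"], crackle_pred["pred"], positive),
        "breath": EvalMetrics.from_predictions(
            breath_pred["group"], breath_pred["pred"], positive),
        "patient": EvalMetrics.from_predictions(
            patient_pred["group"], patient_pred["pred"], positive),
    }
    return CVResult(
        task=task, kind=kind, mode=mode, k=k_eff, metrics=metrics,
        crackle_predictions=crackle_pred, breath_predictions=breath_pred,
        patient_predictions=patient_pred, fold_of_patient=fold_of,
        zero_crackle_breaths=zero_breaths, excluded_patients=excluded,
    )
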