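"""Random-forest evaluation of a candidate-biomarker panel.

The evaluation design reproduces a small-cohort compromise: with only a
handful of controls available, the forest is trained on *all* controls plus
a seed-random subset of cases, then tested on the very same controls plus
the held-out cases. Only the case samples are therefore truly out-of-sample;
specificity estimates are optimistic because the controls are reused. Every
report carries this caveat in its metadata.

The forest itself is scikit-learn's RandomForestClassifier with bootstrap
bagging and an out-of-bag error estimate; class probabilities are the
ensemble vote fractions, thresholded at 0.5 for the confusion matrix and
swept for the ROC curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.metrics import auc, confusion_matrix, roc_curve

from .tables import FeatureTable

CONTROL_REUSE_CAVEAT = (
    "Controls are reused between training and testing (limited control "
    "availability); specificity is therefore an optimistic estimate."
)


@dataclass(frozen=True)
class SplitSpec:
    """Asymmetric train/test split: all controls in both sets, cases split."""

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    n_train_cases: int
    seed: int


@dataclass
class ClassifierReport:
    """Test-set performance of the panel forest."""

    sensitivity: float
    specificity: float
    oob_error: float
    auc: float
    confusion: pd.DataFrame          # actual x predicted counts
    importances: pd.Series           # ranked, descending
    roc_points: pd.DataFrame         # fpr, tpr, threshold
    n_test: int
    caveat: str = CONTROL_REUSE_CAVEAT

    def to_dict(self) -> dict:
        return {
            "sensitivity": round(self.sensitivity, 4),
            "specificity": round(self.specificity, 4),
            "oob_error": round(self.oob_error, 4),
            "auc": round(self.auc, 4),
            "confusion": {
                str(i): {str(c): int(v) for c, v in row.items()}
                for i, row in self.confusion.iterrows()
            },
            "importances": {k: float(v) for k, v in self.importances.items()},
            "n_test": self.n_test,
            "caveat": self.caveat,
        }


def make_split(
    human_table: FeatureTable,
    case_label: str = "OPMD",
    control_label: str = "Control",
    n_train_cases: int = 14,
    seed: int = 0,
) -> SplitSpec:
    """Build the control-reusing split from a human cohort table.

    Training set: all controls plus ``n_train_cases`` seed-randomly chosen
    cases; test set: the same controls plus every remaining case.
    """
    meta = human_table.sample_meta
    analytical = meta[meta["role"] == "analytical"]
    controls = list(analytical.index[analytical["group"] == control_label])
    cases = list(analytical.index[analytical["group"] == case_label])
    if len(cases) <= n_train_cases:
        raise ValueError(
            f"need more than n_train_cases={n_train_cases} cases to leave a "
            f"test set; cohort has {len(cases)}"
        )
    rng = np.random.default_rng(seed)
    train_cases = list(rng.choice(cases, size=n_train_cases, replace=False))
    test_cases = [c for c in cases if c not in set(train_cases)]
    return SplitSpec(
        train_ids=tuple(controls + train_cases),
        test_ids=tuple(controls + test_cases),
        n_train_cases=n_train_cases,
        seed=seed,
    )


def train_forest(
    X_train: np.ndarray,
    y_train,
    n_trees: int = 500,
    mtry: int | None = None,
    seed: int = 0,
) -> tuple[RandomForestClassifier, float]:
    """Fit the bagged forest and return it with its out-of-bag error."""
    y_train = np.asarray(y_train)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training set contains a single class")
    p = np.asarray(X_train).shape[1]
    max_features = mtry if mtry is not None else max(1, int(np.sqrt(p)))
    model = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=max_features,
        oob_score=True,
        bootstrap=True,
        random_state=int(seed),
        n_jobs=1,
    )
    model.fit(np.asarray(X_train, dtype=float), y_train)
    return model, float(1.0 - model.oob_score_)


def evaluate(
    model: RandomForestClassifier,
    X_test: np.ndarray,
    y_test,
    case_label: str = "OPMD",
    oob_error: float = float("nan"),
    importances: pd.Series | None = None,
) -> ClassifierReport:
    """Score the fitted forest on the test set.

    Sensitivity = TP/(TP+FN) with the case class as positive; the ROC sweeps
    the forest's case-vote fraction, with AUC by the trapezoid rule.
    """
    X_test = np.asarray(X_test, dtype=float)
    y_test = np.asarray(y_test)
    labels = list(model.classes_)
    if case_label not in labels:
        raise ValueError(f"case label {case_label!r} unknown to the model")
    if len(np.unique(y_test)) < 2:
        raise ValueError("single-class test set: sensitivity/specificity undefined")
    control_label = next(l for l in labels if l != case_label)
    case_col = labels.index(case_label)
    votes = model.predict_proba(X_test)[:, case_col]
    predicted = np.where(votes >= 0.5, case_label, control_label)

    order = [case_label, control_label]
    cm = confusion_matrix(y_test, predicted, labels=order)
    tp, fn = int(cm[0, 0]), int(cm[0, 1])
    fp, tn = int(cm[1, 0]), int(cm[1, 1])
    fpr, tpr, thr = roc_curve(y_test, votes, pos_label=case_label)
    confusion = pd.DataFrame(
        cm,
        index=pd.Index(order, name="actual"),
        columns=pd.Index(order, name="predicted"),
    )
    if importances is None:
        importances = pd.Series(dtype=float)
    return ClassifierReport(
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        oob_error=oob_error,
        auc=float(auc(fpr, tpr)),
        confusion=confusion,
        importances=importances,
        roc_points=pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}),
        n_test=len(y_test),
    )


def variable_importance(
    model: RandomForestClassifier,
    X_train: np.ndarray,
    y_train,
    feature_ids,
    mode: str = "permutation",
    n_repeats: int = 20,
    seed: int = 0,
) -> pd.Series:
    """Ranked feature importances (descending).

    ``permutation`` (default): mean accuracy drop over seeded feature
    permutations; ``impurity``: the forest's mean impurity decrease.
    """
    if mode == "impurity":
        values = model.feature_importances_
    elif mode == "permutation":
        res = permutation_importance(
            model,
            np.asarray(X_train, dtype=float),
            np.asarray(y_train),
            n_repeats=n_repeats,
            random_state=int(seed),
            scoring="accuracy",
        )
        values = res.importances_mean
    else:
        raise ValueError(f"unknown importance mode {mode!r}")
    return pd.Series(values, index=list(feature_ids)).sort_values(ascending=False)


def evaluate_panel(
    human_table: FeatureTable,
    panel: list[str],
    case_label: str = "OPMD",
    control_label: str = "Control",
    n_train_cases: int = 14,
    n_trees: int = 500,
    seed: int = 0,
    importance_mode: str = "permutation",
) -> tuple[ClassifierReport, SplitSpec]:
    """End-to-end panel evaluation: split, train, importances, test report."""
    sub = human_table.select_features(panel)
    split = make_split(
        sub, case_label=case_label, control_label=control_label,
        n_train_cases=n_train_cases, seed=seed,
    )
    X = np.log10(np.clip(sub.intensities.to_numpy(dtype=float), 1e-12, None))
    frame = pd.DataFrame(X, index=sub.intensities.index, columns=sub.feature_ids)
    y = sub.sample_meta["group"]
    X_train, y_train = frame.loc[list(split.train_ids)], y.loc[list(split.train_ids)]
    X_test, y_test = frame.loc[list(split.test_ids)], y.loc[list(split.test_ids)]
    model, oob = train_forest(X_train, y_train, n_trees=n_trees, seed=seed)
    imp = variable_importance(
        model, X_train, y_train, sub.feature_ids, mode=importance_mode, seed=seed
    )
    report = evaluate(
        model, X_test, y_test, case_label=case_label, oob_error=oob, importances=imp
    )
    return report, split
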