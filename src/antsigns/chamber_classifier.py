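"""Chamber classification by majority vote over pairwise linear SVMs.

Three tasks of increasing detail label the 2-D (light_norm, heavy_norm)
chamber features: (1) internal versus external (entrance and arena)
chambers, (2) the three inner-chamber classes (worker, queen, entrance),
(3) four classes including the arena. One soft-margin linear separator is
fitted per unordered class pair; prediction is by majority vote with
deterministic signed-margin tie-breaking. Evaluation uses grouped
leave-one-experiment-out cross-validation — folds are whole experiments, so
samples from one experiment never straddle the train/test split — plus a
disjoint held-out test set.

Accuracy is reported both plainly (per-sample) and balanced (macro-averaged
recall). Balanced accuracy is the chance-calibrated metric: any classifier
independent of the labels has expected balanced accuracy exactly one over
the number of classes, regardless of class frequencies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .errors import LeakageError, ParameterError, TrainingError

__all__ = [
    "TASK_CLASSES",
    "VoteEnsemble",
    "task_labels",
    "train_ensemble",
    "predict",
    "loo_by_experiment",
    "evaluate_test",
]

log = logging.getLogger(__name__)

FEATURE_COLUMNS = ["light_norm", "heavy_norm"]

_ROLE_TO_TASK = {
    1: {
        "queen": "internal",
        "worker_brood": "internal",
        "worker_nonbrood": "internal",
        "entrance": "external",
        "arena": "external",
    },
    2: {
        "queen": "queen",
        "worker_brood": "worker",
        "worker_nonbrood": "worker",
        "entrance": "entrance",
        "arena": None,  # arena samples are dropped in the inner-chamber task
    },
    3: {
        "queen": "queen",
        "worker_brood": "worker",
        "worker_nonbrood": "worker",
        "entrance": "entrance",
        "arena": "arena",
    },
}

TASK_CLASSES = {
    1: ("external", "internal"),
    2: ("entrance", "queen", "worker"),
    3: ("arena", "entrance", "queen", "worker"),
}


def task_labels(features: pd.DataFrame, task: int) -> pd.DataFrame:
    """Attach the task's class label to each chamber sample (arena samples
    are dropped in task 2)."""
    if task not in _ROLE_TO_TASK:
        raise ParameterError(f"task must be 1, 2 or 3, got {task}")
    mapping = _ROLE_TO_TASK[task]
    unknown = set(features["role"]) - set(mapping)
    if unknown:
        raise ParameterError(f"unknown role(s): {sorted(unknown)}")
    out = features.copy()
    out["label"] = out["role"].map(mapping)
    return out[out["label"].notna()].reset_index(drop=True)


@dataclass
class _PairSeparator:
    lo: str
    hi: str
    weights: np.ndarray  # decision w.x + b > 0 favours `hi`
    offset: float
    margin: float

    def decision(self, X: np.ndarray) -> np.ndarray:
        return X @ self.weights + self.offset

    def signed_distance(self, X: np.ndarray) -> np.ndarray:
        return self.decision(X) / np.linalg.norm(self.weights)


@dataclass
class VoteEnsemble:
    """One linear separator per unordered class pair plus vote bookkeeping."""

    classes: tuple
    separators: dict  # (lo, hi) -> _PairSeparator
    regularization: float
    training_experiments: tuple = ()


def train_ensemble(
    features: pd.DataFrame,
    regularization: float = 1.0,
) -> VoteEnsemble:
    """Fit a soft-margin linear SVM on every class pair's samples.

    `features` needs FEATURE_COLUMNS plus a `label` column (and optionally
    experiment_id, recorded for leakage checks). Deterministic given inputs.
    """
    if regularization <= 0:
        raise ParameterError("regularization must be positive")
    classes = tuple(sorted(features["label"].unique()))
    if len(classes) < 2:
        raise TrainingError(f"need >= 2 classes, got {classes}")
    counts = features["label"].value_counts()
    thin = [c for c in classes if counts[c] < 2]
    if thin:
        raise TrainingError(f"class(es) with < 2 samples: {thin}")
    X = features[FEATURE_COLUMNS].to_numpy(float)
    if not np.isfinite(X).all():
        raise TrainingError("non-finite feature values")
    y = features["label"].to_numpy(object)
    separators = {}
    for lo, hi in combinations(classes, 2):
        sel = (y == lo) | (y == hi)
        svc = SVC(kernel="linear", C=regularization)
        svc.fit(X[sel], y[sel])
        w = svc.coef_[0].copy()
        b = float(svc.intercept_[0])
        # sklearn orients the decision toward classes_[1]; normalize to `hi`
        if svc.classes_[1] != hi:
            w, b = -w, -b
        separators[(lo, hi)] = _PairSeparator(
            lo=lo, hi=hi, weights=w, offset=b, margin=2.0 / np.linalg.norm(w)
        )
    exps = (
        tuple(sorted(features["experiment_id"].unique()))
        if "experiment_id" in features
        else ()
    )
    return VoteEnsemble(
        classes=classes,
        separators=separators,
        regularization=regularization,
        training_experiments=exps,
    )


def predict(ensemble: VoteEnsemble, features) -> pd.DataFrame:
    """Majority vote over the pairwise separators.

    Vote ties (possible with >= 3 classes) are broken by the largest sum of
    signed distances to the tied classes' separators, then lexicographically;
    tied samples are flagged in the `tie` column.
    """
    if isinstance(features, pd.DataFrame):
        X = features[FEATURE_COLUMNS].to_numpy(float)
    else:
        X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if not np.isfinite(X).all():
        raise ParameterError("feature matrix contains non-finite values")
    classes = list(ensemble.classes)
    votes = pd.DataFrame(0, index=range(len(X)), columns=classes)
    margin_sum = pd.DataFrame(0.0, index=range(len(X)), columns=classes)
    for (lo, hi), sep in ensemble.separators.items():
        d = sep.signed_distance(X)
        votes[hi] += (d > 0).astype(int)
        votes[lo] += (d <= 0).astype(int)
        margin_sum[hi] += d
        margin_sum[lo] -= d
    vmax = votes.max(axis=1)
    labels = []
    ties = []
    for i in range(len(X)):
        tied = [c for c in classes if votes.at[i, c] == vmax[i]]
        if len(tied) == 1:
            labels.append(tied[0])
            ties.append(False)
        else:
            ms = margin_sum.loc[i, tied]
            best = ms.index[np.argmax(ms.to_numpy())]
            labels.append(best)
            ties.append(True)
    return pd.DataFrame({"prediction": labels, "tie": ties})


def _confusion(y_true, y_pred, classes) -> pd.DataFrame:
    cm = pd.DataFrame(0, index=list(classes), columns=list(classes))
    for t, p in zip(y_true, y_pred):
        cm.at[t, p] += 1
    cm.index.name = "true"
    cm.columns.name = "predicted"
    return cm


def _accuracies(cm: pd.DataFrame) -> dict:
    total = cm.to_numpy().sum()
    correct = np.trace(cm.to_numpy())
    row_sums = cm.sum(axis=1)
    recalls = [
        cm.at[c, c] / row_sums[c] for c in cm.index if row_sums[c] > 0
    ]
    return {
        "accuracy": correct / total if total else float("nan"),
        "balanced_accuracy": float(np.mean(recalls)) if recalls else float("nan"),
    }


def loo_by_experiment(
    features: pd.DataFrame,
    task: int,
    regularization: float = 1.0,
) -> dict:
    """Leave-one-experiment-out evaluation of the pairwise-vote ensemble.

    Each fold holds out all samples of one experiment; folds whose training
    split loses a class entirely are skipped with a warning. Returns plain
    and balanced accuracy plus the pooled confusion matrix.
    """
    labelled = task_labels(features, task)
    experiments = sorted(labelled["experiment_id"].unique())
    if len(experiments) < 2:
        raise ParameterError("need >= 2 experiments for leave-one-out")
    classes = tuple(sorted(labelled["label"].unique()))
    y_true, y_pred = [], []
    skipped = []
    for exp in experiments:
        train = labelled[labelled["experiment_id"] != exp]
        test = labelled[labelled["experiment_id"] == exp]
        if set(train["label"].unique()) != set(classes):
            log.warning("fold %r leaves a class absent from training; skipped", exp)
            skipped.append(exp)
            continue
        ensemble = train_ensemble(train, regularization)
        pred = predict(ensemble, test)
        y_true.extend(test["label"])
        y_pred.extend(pred["prediction"])
    cm = _confusion(y_true, y_pred, classes)
    return {
        "task": task,
        **_accuracies(cm),
        "confusion": cm,
        "n_folds": len(experiments) - len(skipped),
        "skipped_folds": skipped,
        "n_samples": len(y_true),
    }


def evaluate_test(ensemble: VoteEnsemble, test: pd.DataFrame) -> dict:
    """Accuracy and confusion matrix on a disjoint test set.

    Raises LeakageError if the test set shares experiment ids with the
    ensemble's training set.
    """
    if len(test) == 0:
        raise ParameterError("test set is empty")
    if "experiment_id" in test and ensemble.training_experiments:
        overlap = set(test["experiment_id"]) & set(ensemble.training_experiments)
        if overlap:
            raise LeakageError(f"test set shares experiment(s) with training: {sorted(overlap)}")
    foreign = set(test["label"]) - set(ensemble.classes)
    if foreign:
        raise ParameterError(f"test label(s) unknown to the ensemble: {sorted(foreign)}")
    pred = predict(ensemble, test)
    cm = _confusion(test["label"], pred["prediction"], ensemble.classes)
    per_class = {
        c: float(cm.at[c, c] / cm.loc[c].sum()) if cm.loc[c].sum() else float("nan")
        for c in ensemble.classes
    }
    return {
        **_accuracies(cm),
        "per_class_accuracy": per_class,
        "confusion": cm,
        "n_ties": int(pred["tie"].sum()),
    }
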