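"""Heart-wise lesion classification from optical-index feature vectors.

The protocol: assemble one feature vector per contact-filtered spectrum,
split hearts (not spectra) into training and test groups, run five-fold
cross-validation grouped by heart within the training set for each of
five model families (logistic regression, kNN, gradient boosting, SVM,
random forest), and form the final predictor as the average of the five
fold-models' predicted probabilities.  Inverse-frequency class weights
counter the lesion/nonlesion imbalance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import HistGradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GroupKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import stats
from .types import ValidationError

MODEL_KINDS = ("logistic", "knn", "gradient_boosting", "svm", "random_forest")

DEFAULT_FEATURES = ("loi0", "soi1", "loi8", "soi3", "soi4")

DEFAULT_HYPERPARAMS: dict[str, dict] = {
    "logistic": {"max_iter": 2000},
    "knn": {"n_neighbors": 15},
    "gradient_boosting": {"max_iter": 200},
    "svm": {"kernel": "rbf", "C": 1.0},
    "random_forest": {"n_estimators": 300, "min_samples_leaf": 20},
}


def class_weights(y: np.ndarray) -> dict[int, float]:
    """Inverse class-frequency weights, renormalized to mean 1 per sample."""
    y = np.asarray(y)
    n = len(y)
    n1 = int(y.sum())
    n0 = n - n1
    return {0: n / (2.0 * n0), 1: n / (2.0 * n1)}


def build_dataset(
    table: pd.DataFrame, feature_names: tuple[str, ...] = DEFAULT_FEATURES
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    """Feature matrix, labels (1 = lesion), heart ids, and class counts."""
    bad = set(table["label"]) - {"lesion", "nonlesion"}
    if bad:
        raise ValidationError(f"unknown labels present: {sorted(bad)}")
    missing = [f for f in feature_names if f not in table.columns]
    if missing:
        raise ValidationError(f"missing features: {missing}")
    X = table[list(feature_names)].to_numpy(dtype=float)
    y = (table["label"] == "lesion").to_numpy(dtype=int)
    hearts = table["heart_id"].to_numpy()
    counts = {
        "n": len(y),
        "n_lesion": int(y.sum()),
        "n_nonlesion": int(len(y) - y.sum()),
        "lesion_fraction": float(y.mean()),
    }
    return X, y, hearts, counts


def _make_model(kind: str, weights: dict[int, float], seed: int, params: dict):
    p = dict(DEFAULT_HYPERPARAMS[kind])
    p.update(params)
    if kind == "logistic":
        return make_pipeline(
            StandardScaler(), LogisticRegression(class_weight=weights, **p)
        )
    if kind == "knn":
        return make_pipeline(StandardScaler(), KNeighborsClassifier(**p))
    if kind == "gradient_boosting":
        return HistGradientBoostingClassifier(random_state=seed, **p)
    if kind == "svm":
        return make_pipeline(
            StandardScaler(),
            SVC(probability=True, class_weight=weights, random_state=seed, **p),
        )
    if kind == "random_forest":
        return RandomForestClassifier(
            class_weight=weights, random_state=seed, n_jobs=1, **p
        )
    raise ValidationError(f"unknown model kind {kind!r}; expected one of {MODEL_KINDS}")


@dataclass
class TrainedClassifier:
    """Ensemble of per-fold fitted models; predicts averaged probabilities."""

    kind: str
    feature_names: tuple[str, ...]
    weights: dict[int, float]
    seed: int
    fold_models: list = field(default_factory=list)
    fold_hearts: list = field(default_factory=list)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Mean lesion probability across the five fold-models, in [0, 1]."""
        X = np.asarray(X, dtype=float)
        probs = np.stack([m.predict_proba(X)[:, 1] for m in self.fold_models])
        if self.kind == "knn":
            # kNN has no class weights; reweight the vote posterior instead
            w0, w1 = self.weights[0], self.weights[1]
            probs = (w1 * probs) / (w1 * probs + w0 * (1 - probs))
        return probs.mean(axis=0)


def train_classifier(
    X: np.ndarray,
    y: np.ndarray,
    hearts: np.ndarray,
    kind: str = "random_forest",
    seed: int = 0,
    n_folds: int = 5,
    feature_names: tuple[str, ...] = DEFAULT_FEATURES,
    hyperparams: dict | None = None,
) -> TrainedClassifier:
    """Fit one model kind with heart-grouped cross-validation folds."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    hearts = np.asarray(hearts)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValidationError("both classes must be present")
    if len(np.unique(hearts)) < n_folds:
        raise ValidationError(f"need >= {n_folds} hearts for heart-grouped folds")
    weights = class_weights(y)
    clf = TrainedClassifier(
        kind=kind, feature_names=tuple(feature_names), weights=weights, seed=seed
    )
    gkf = GroupKFold(n_splits=n_folds)
    for fold, (tr, _va) in enumerate(gkf.split(X, y, groups=hearts)):
        if len(np.unique(y[tr])) < 2:
            raise ValidationError(f"fold {fold} training split has a single class")
        model = _make_model(kind, weights, seed + fold, hyperparams or {})
        if kind == "gradient_boosting":
            sw = np.where(y[tr] == 1, weights[1], weights[0])
            model.fit(X[tr], y[tr], sample_weight=sw)
        else:
            model.fit(X[tr], y[tr])
        clf.fold_models.append(model)
        clf.fold_hearts.append(sorted(set(hearts[tr])))
    return clf


@dataclass
class Evaluation:
    sensitivity: float
    specificity: float
    auc: float
    tp: int
    fp: int
    tn: int
    fn: int
    threshold: float

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def evaluate(
    clf: TrainedClassifier,
    X: np.ndarray,
    y: np.ndarray,
    threshold: float = 0.5,
) -> Evaluation:
    """Sensitivity/specificity at a probability threshold, plus ROC AUC."""
    if not 0.0 <= threshold <= 1.0:
        raise ValidationError("threshold must lie in [0, 1]")
    y = np.asarray(y, dtype=int)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValidationError("both classes must be present in evaluation set")
    p = clf.predict_proba(X)
    pred = p >= threshold
    pos = y == 1
    tp = int(np.sum(pred & pos))
    fn = int(np.sum(~pred & pos))
    tn = int(np.sum(~pred & ~pos))
    fp = int(np.sum(pred & ~pos))
    auc, _, _ = stats.roc_auc(p, pos)
    return Evaluation(
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        auc=auc,
        tp=tp, fp=fp, tn=tn, fn=fn,
        threshold=threshold,
    )
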