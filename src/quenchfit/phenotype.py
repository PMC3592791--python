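"""Decision-tree classification of functional receptor phenotypes.

Cells from pure populations, described by their fitted (EC50, Hill slope),
train an axis-aligned decision tree (entropy splits, minimum leaf size 5 —
C4.5-like behavior on two numeric features); stratified k-fold
cross-validation estimates per-class accuracy, the final model is refit on
the full training set, and cells from mixed populations are assigned a class
so subpopulation fractions can be recovered.  EC50 enters in log10 (a
monotone transform that stabilizes reported split thresholds).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

__all__ = ["PhenotypeModel", "train_classifier", "classify", "FEATURES"]

FEATURES = ("ec50", "slope")


@dataclass
class PhenotypeModel:
    tree: DecisionTreeClassifier
    classes: list
    features: tuple = FEATURES
    folds: int = 10
    seed: int = 0
    cv_accuracy_per_class: dict = field(default_factory=dict)
    cv_confusion: np.ndarray | None = None

    def to_json(self) -> str:
        t = self.tree.tree_
        nodes = []
        for i in range(t.node_count):
            if t.children_left[i] == -1:
                counts = t.value[i][0] * t.weighted_n_node_samples[i]
                nodes.append({
                    "leaf": True,
                    "class": self.classes[int(np.argmax(t.value[i][0]))],
                    "counts": {c: int(round(v)) for c, v in zip(self.classes, counts)},
                })
            else:
                nodes.append({
                    "leaf": False,
                    "feature": self._feature_name(int(t.feature[i])),
                    "threshold": float(t.threshold[i]),
                    "left": int(t.children_left[i]),
                    "right": int(t.children_right[i]),
                })
        return json.dumps({
            "features": list(self.features),
            "classes": list(self.classes),
            "folds": self.folds,
            "seed": self.seed,
            "cv_accuracy_per_class": self.cv_accuracy_per_class,
            "cv_confusion": None if self.cv_confusion is None else self.cv_confusion.tolist(),
            "nodes": nodes,
        }, indent=2)

    def _feature_name(self, idx: int) -> str:
        name = self.features[idx]
        return f"log10_{name}" if name == "ec50" else name


def _design_matrix(table: pd.DataFrame, features) -> np.ndarray:
    missing = [f for f in features if f not in table.columns]
    if missing:
        raise ValueError(f"missing feature column(s): {missing}")
    X = table[list(features)].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    if "ec50" in features:
        j = list(features).index("ec50")
        X[:, j] = np.log10(X[:, j])
    return X


def _new_tree(seed: int) -> DecisionTreeClassifier:
    return DecisionTreeClassifier(criterion="entropy", min_samples_leaf=5,
                                  random_state=seed)


def train_classifier(train: pd.DataFrame, folds: int = 10, seed: int = 0,
                     features=FEATURES, label_column: str = "label") -> PhenotypeModel:
    """Train the phenotype tree with stratified k-fold cross-validation.

    ``train`` needs the feature columns and a class label column; every
    class must have at least ``folds`` members and there must be >= 2
    classes.  The returned model stores per-class CV accuracy and the pooled
    confusion matrix, and is refit on the full training set.  Deterministic
    per seed.
    """
    y = train[label_column].to_numpy()
    classes = sorted(pd.unique(y))
    if len(classes) < 2:
        raise ValueError(f"need >= 2 classes, got {classes}")
    counts = pd.Series(y).value_counts()
    small = counts[counts < folds]
    if len(small):
        raise ValueError(f"class(es) smaller than fold count {folds}: {dict(small)}")
    X = _design_matrix(train, features)

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    y_true_all, y_pred_all = [], []
    for tr_idx, te_idx in skf.split(X, y):
        fold_tree = _new_tree(seed).fit(X[tr_idx], y[tr_idx])
        y_true_all.append(y[te_idx])
        y_pred_all.append(fold_tree.predict(X[te_idx]))
    y_true = np.concatenate(y_true_all)
    y_pred = np.concatenate(y_pred_all)
    cm = confusion_matrix(y_true, y_pred, labels=classes)
    per_class = {
        c: float(cm[i, i] / cm[i].sum()) if cm[i].sum() else float("nan")
        for i, c in enumerate(classes)
    }
    final = _new_tree(seed).fit(X, y)
    return PhenotypeModel(tree=final, classes=classes, features=tuple(features),
                          folds=folds, seed=seed,
                          cv_accuracy_per_class=per_class, cv_confusion=cm)


def classify(model: PhenotypeModel, cells: pd.DataFrame):
    """Assign a phenotype label to each cell; returns (labels, fraction table).

    Fractions are per-class shares of the classified cells; an empty input
    gives an empty label array and NaN fractions.
    """
    if len(cells) == 0:
        fractions = pd.Series({c: float("nan") for c in model.classes}, name="fraction")
        return np.array([], dtype=object), fractions
    X = _design_matrix(cells, model.features)
    labels = model.tree.predict(X)
    counts = pd.Series(labels).value_counts()
    fractions = pd.Series(
        {c: counts.get(c, 0) / len(labels) for c in model.classes}, name="fraction"
    )
    return labels, fractions
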