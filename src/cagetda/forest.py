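"""Supervised cage identification with a random forest on fingerprints.

Protocol: 100 trees ("base" hyperparameters otherwise), stratified 85/15
train/test split, majority-vote decision at probability 0.5.  Both overall
and class-balanced held-out accuracies are recorded, since small fixture
populations can be imbalanced.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import balanced_accuracy_score, confusion_matrix
from sklearn.model_selection import train_test_split

DEFAULT_N_ESTIMATORS = 100
DEFAULT_TEST_FRACTION = 0.15
CLASSES = ("cage", "non_cage")


@dataclass
class TrainedModel:
    forest: RandomForestClassifier
    feature_length: int
    classes: tuple[str, ...]
    metadata: dict


def train_classifier(
    X: np.ndarray,
    y: list[str] | np.ndarray,
    test_fraction: float = DEFAULT_TEST_FRACTION,
    n_estimators: int = DEFAULT_N_ESTIMATORS,
    seed: int = 0,
    **tree_kwargs,
) -> tuple[TrainedModel, float]:
    """Train on a stratified split; returns (model, held-out accuracy)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    if len(X) < 10:
        raise ValueError("need at least 10 rows to train")
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=test_fraction, random_state=seed, stratify=y
    )
    forest = RandomForestClassifier(
        n_estimators=n_estimators, random_state=seed, **tree_kwargs
    )
    forest.fit(X_tr, y_tr)
    pred = forest.predict(X_te)
    accuracy = float(np.mean(pred == y_te))
    model = TrainedModel(
        forest=forest,
        feature_length=X.shape[1],
        classes=tuple(classes),
        metadata={
            "seed": seed,
            "test_fraction": test_fraction,
            "n_estimators": n_estimators,
            "n_train": len(X_tr),
            "n_test": len(X_te),
            "train_accuracy": float(np.mean(forest.predict(X_tr) == y_tr)),
            "test_accuracy": accuracy,
            "test_balanced_accuracy": float(balanced_accuracy_score(y_te, pred)),
        },
    )
    return model, accuracy


def predict(model: TrainedModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Labels plus cage probability (fraction of trees voting cage) per row."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.feature_length:
        raise ValueError(
            f"feature length {X.shape[1]} does not match the model's {model.feature_length}"
        )
    labels = model.forest.predict(X)
    proba = model.forest.predict_proba(X)
    cage_col = list(model.forest.classes_).index("cage") if "cage" in model.forest.classes_ else 0
    return labels, proba[:, cage_col]


def evaluate(
    model: TrainedModel, X: np.ndarray, y: list[str] | np.ndarray,
    ids: list[str] | None = None,
) -> dict:
    """Accuracy, 2×2 confusion counts and the false-negative id list."""
    y = np.asarray(y, dtype=object)
    labels, _ = predict(model, X)
    acc = float(np.mean(labels == y))
    cm = confusion_matrix(y, labels, labels=list(CLASSES))
    if ids is None:
        ids = [str(i) for i in range(len(y))]
    false_negatives = [
        ids[i] for i in range(len(y)) if y[i] == "cage" and labels[i] == "non_cage"
    ]
    return {
        "accuracy": acc,
        "balanced_accuracy": float(balanced_accuracy_score(y, labels)),
        "confusion": {"cage": {"cage": int(cm[0, 0]), "non_cage": int(cm[0, 1])},
                      "non_cage": {"cage": int(cm[1, 0]), "non_cage": int(cm[1, 1])}},
        "false_negatives": false_negatives,
    }


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Versioned archive (joblib) plus a JSON parameter sidecar."""
    path = Path(path)
    joblib.dump({"forest": model.forest, "feature_length": model.feature_length,
                 "classes": model.classes, "metadata": model.metadata, "format": 1}, path)
    Path(str(path) + ".json").write_text(json.dumps(model.metadata, indent=1) + "\n")


def load_model(path: str | Path) -> TrainedModel:
    payload = joblib.load(path)
    return TrainedModel(
        forest=payload["forest"],
        feature_length=payload["feature_length"],
        classes=tuple(payload["classes"]),
        metadata=payload["metadata"],
    )
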