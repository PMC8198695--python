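"""Random-forest false-positive filter over candidate feature vectors.

Positives for training are high-confidence open regions (in practice,
TSS windows of housekeeping genes; in simulation, planted OCRs);
negatives are regions with abnormal waveform distortion that mimic the
coverage dip of an OCR without its regular flanking arrays.  The 800
labelled windows are split 1:1 into training and test halves, with 30%
of the training half held out for validation.  The forest uses 100
trees, Gini impurity and a minimum split size of 2; candidates are kept
when their positive-class probability reaches the keep threshold
(default 0.5).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

DEFAULT_N_TREES = 100
DEFAULT_KEEP_THRESHOLD = 0.5


@dataclass
class DataSplit:
    """Stratified train/validation/test partition of a labelled set."""

    X_train: pd.DataFrame
    y_train: np.ndarray
    X_val: pd.DataFrame
    y_val: np.ndarray
    X_test: pd.DataFrame
    y_test: np.ndarray


@dataclass
class RFModel:
    """A fitted forest plus the feature schema it was trained on."""

    estimator: RandomForestClassifier
    feature_names: tuple[str, ...]
    seed: int
    params: dict = field(default_factory=dict)

    def save(self, path: str | os.PathLike) -> None:
        """Persist the estimator (joblib) with a JSON schema sidecar."""
        import sklearn

        joblib.dump(self.estimator, path)
        sidecar = {
            "feature_names": list(self.feature_names),
            "seed": self.seed,
            "params": self.params,
            "sklearn_version": sklearn.__version__,
        }
        with open(str(path) + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "RFModel":
        estimator = joblib.load(path)
        with open(str(path) + ".json") as fh:
            sidecar = json.load(fh)
        return cls(
            estimator=estimator,
            feature_names=tuple(sidecar["feature_names"]),
            seed=int(sidecar["seed"]),
            params=sidecar.get("params", {}),
        )


def split_data(
    X: pd.DataFrame,
    y: Sequence[int],
    seed: int,
    test_frac: float = 0.5,
    val_frac_of_train: float = 0.3,
) -> DataSplit:
    """Stratified 1:1 train/test split, then 30% of train as validation."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2 or min(np.bincount(y)) < 2:
        raise ValueError("need at least 2 samples per class")
    X_train, X_test, y_train, y_test = train_test_split(
        X, y, test_size=test_frac, stratify=y, random_state=seed
    )
    X_fit, X_val, y_fit, y_val = train_test_split(
        X_train,
        y_train,
        test_size=val_frac_of_train,
        stratify=y_train,
        random_state=seed,
    )
    return DataSplit(X_fit, y_fit, X_val, y_val, X_test, y_test)


def train(
    X: pd.DataFrame,
    y: Sequence[int],
    seed: int = 0,
    n_trees: int = DEFAULT_N_TREES,
) -> RFModel:
    """Fit the false-positive filter (100 trees, Gini, min split 2)."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    if not np.all(np.isfinite(np.asarray(X, dtype=float))):
        raise ValueError("features must be finite")
    est = RandomForestClassifier(
        n_estimators=n_trees,
        criterion="gini",
        min_samples_split=2,
        random_state=seed,
    )
    est.fit(X, y)
    return RFModel(
        estimator=est,
        feature_names=tuple(X.columns),
        seed=seed,
        params={"n_trees": n_trees, "criterion": "gini", "min_samples_split": 2},
    )


def _check_schema(model: RFModel, X: pd.DataFrame) -> pd.DataFrame:
    have = tuple(X.columns)
    want = model.feature_names
    if have == want:
        return X
    missing = [c for c in want if c not in X.columns]
    extra = [c for c in X.columns if c not in want]
    if missing or extra:
        raise ValueError(
            f"feature schema mismatch: missing={missing}, extra={extra}"
        )
    return X[list(want)]  # same columns, different order


def predict_proba(model: RFModel, X: pd.DataFrame) -> np.ndarray:
    """Positive-class probability for each row, after schema validation."""
    X = _check_schema(model, X)
    pos_idx = int(np.nonzero(model.estimator.classes_ == 1)[0][0])
    return model.estimator.predict_proba(X)[:, pos_idx]


def apply_filter(
    model: RFModel,
    X: pd.DataFrame,
    threshold: float = DEFAULT_KEEP_THRESHOLD,
) -> tuple[np.ndarray, np.ndarray]:
    """(keep mask, probabilities); a candidate is kept iff p >= threshold."""
    probs = predict_proba(model, X)
    return probs >= threshold, probs


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC via the Mann-Whitney rank statistic (ties averaged)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    r_pos = float(np.sum(ranks[labels == 1]))
    u = r_pos - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def evaluate_roc(
    model: RFModel, X: pd.DataFrame, y: Sequence[int]
) -> dict[str, object]:
    """ROC points plus AUC (computed as the rank statistic)."""
    from sklearn.metrics import roc_curve

    y = np.asarray(y)
    probs = predict_proba(model, X)
    fpr, tpr, thresholds = roc_curve(y, probs)
    return {
        "fpr": fpr,
        "tpr": tpr,
        "thresholds": thresholds,
        "auc": rank_auc(probs, y),
    }
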