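"""Simulation-backed training harness for the false-positive classifier.

Real-data training uses housekeeping-gene TSS windows as positives; on
synthetic data the planted OCRs play that role and planted distortion
artefacts (coverage dips without regular flanking nucleosome arrays)
play the negatives.  The harness plants the labelled regions, extracts
feature vectors with exactly the pipeline's per-tile machinery, splits
them 1:1 train/test with a 30% validation hold-out, and fits the forest.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from . import rf_filter as rf
from .pipeline import PipelineConfig, features_for_windows
from .simulate import SimConfig, simulate, training_genome


def labelled_centers(config: SimConfig) -> tuple[list[tuple[str, int]], np.ndarray]:
    """(window centres, labels) for a config with planted OCRs/distortions."""
    centers: list[tuple[str, int]] = []
    labels: list[int] = []
    for a, b in config.ocr_intervals:
        centers.append((config.contig, (a + b) // 2))
        labels.append(1)
    for a, b in config.distortion_intervals:
        centers.append((config.contig, (a + b) // 2))
        labels.append(0)
    return centers, np.asarray(labels)


def training_features(
    n_pos: int = 400,
    n_neg: int = 400,
    depth: float = 30.0,
    seed: int = 0,
    pipeline_config: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Simulate a labelled genome and return (features, labels)."""
    sim_config = training_genome(n_pos=n_pos, n_neg=n_neg, depth=depth, seed=seed)
    fragments, _ = simulate(sim_config)
    centers, labels = labelled_centers(sim_config)
    cfg = pipeline_config if pipeline_config is not None else PipelineConfig(seed=seed)
    X = features_for_windows(
        fragments,
        centers,
        {sim_config.contig: sim_config.genome_length},
        cfg,
    )
    return X, labels


def train_on_simulation(
    n_pos: int = 400,
    n_neg: int = 400,
    depth: float = 30.0,
    seed: int = 0,
    pipeline_config: PipelineConfig | None = None,
) -> tuple[rf.RFModel, dict]:
    """Train the classifier on simulated labelled windows.

    Returns the fitted model and summary metrics (held-out AUC and
    accuracy on the untouched test half, validation AUC).
    """
    X, y = training_features(n_pos, n_neg, depth, seed, pipeline_config)
    split = rf.split_data(X, y, seed=seed)
    model = rf.train(split.X_train, split.y_train, seed=seed)
    test_roc = rf.evaluate_roc(model, split.X_test, split.y_test)
    val_roc = rf.evaluate_roc(model, split.X_val, split.y_val)
    test_probs = rf.predict_proba(model, split.X_test)
    accuracy = float(np.mean((test_probs >= 0.5) == (split.y_test == 1)))
    metrics = {
        "n_train": int(len(split.y_train)),
        "n_val": int(len(split.y_val)),
        "n_test": int(len(split.y_test)),
        "test_auc": float(test_roc["auc"]),
        "val_auc": float(val_roc["auc"]),
        "test_accuracy": accuracy,
    }
    return model, metrics
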