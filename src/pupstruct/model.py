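"""RBF-kernel support-vector classification of lysine windows.

The classifier is a soft-margin C-SVC with kernel
``exp(-gamma * ||u - v||^2)``, gamma = 0.5 and C = 3 by default. Class
weighting is deliberately absent: imbalance is handled upstream by the
k-NN cleaning stage, not by the loss. Decision scores are the signed
margins, used directly for ROC analysis (no probability calibration).
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from sklearn.svm import SVC

from .encoding import LabeledDataset, NormalizationParams

__all__ = ["SvmConfig", "TrainedModel", "train", "predict", "save_model", "load_model"]

_SERIAL_VERSION = 1


@dataclass(frozen=True)
class SvmConfig:
    """Kernel and regularization settings."""

    kernel: str = "rbf"
    gamma: float = 0.5
    cost: float = 3.0
    formulation: str = "c_classification"

    def __post_init__(self) -> None:
        if self.kernel != "rbf":
            raise ValueError(f"unsupported kernel {self.kernel!r}")
        if self.gamma <= 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")
        if self.cost <= 0:
            raise ValueError(f"cost must be positive, got {self.cost}")
        if self.formulation != "c_classification":
            raise ValueError(f"unsupported formulation {self.formulation!r}")


@dataclass
class TrainedModel:
    """A fitted classifier plus the context needed to apply it safely."""

    svc: SVC
    n_features: int
    config: SvmConfig
    normalization: Optional[NormalizationParams] = None


def train(dataset: LabeledDataset, config: SvmConfig = SvmConfig()) -> TrainedModel:
    """Fit the classifier on a labeled (post-cleaning, normalized) dataset.

    Deterministic for identical input data and config, and invariant to
    the order of training samples (the dual problem has a unique optimum
    for strictly positive-definite RBF kernels).
    """
    dataset.require_labels()
    if dataset.n_pos == 0 or dataset.n_neg == 0:
        raise ValueError(
            f"training requires both classes; got {dataset.n_pos} positives "
            f"and {dataset.n_neg} negatives"
        )
    if dataset.normalization is not None and len(dataset.normalization) != dataset.n_features:
        raise ValueError("normalization params do not match dataset feature count")
    svc = SVC(kernel="rbf", gamma=config.gamma, C=config.cost)
    svc.fit(dataset.X, dataset.y)
    return TrainedModel(
        svc=svc,
        n_features=dataset.n_features,
        config=config,
        normalization=dataset.normalization,
    )


def predict(model: TrainedModel, vectors: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Classify feature vectors; returns (binary labels, decision scores).

    Scores are continuous margins, higher = more pupylated-like; the label
    is 1 iff the score is strictly positive (a score of exactly 0 maps to
    the negative class). The caller is responsible for applying the same
    normalization the model was trained with.
    """
    vectors = np.asarray(vectors, dtype=float)
    if vectors.ndim == 1:
        vectors = vectors.reshape(1, -1)
    if vectors.size == 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=float)
    if vectors.shape[1] != model.n_features:
        raise ValueError(
            f"feature count mismatch: model expects {model.n_features}, "
            f"got {vectors.shape[1]}"
        )
    scores = model.svc.decision_function(vectors)
    labels = (scores > 0).astype(int)
    return labels, scores


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Serialize a trained model to a single versioned file."""
    payload = {
        "format_version": _SERIAL_VERSION,
        "svc": model.svc,
        "n_features": model.n_features,
        "config": model.config,
        "normalization": model.normalization,
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_model(path: str | Path) -> TrainedModel:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    version = payload.get("format_version")
    if version != _SERIAL_VERSION:
        raise ValueError(f"unsupported model file version {version!r}")
    return TrainedModel(
        svc=payload["svc"],
        n_features=payload["n_features"],
        config=payload["config"],
        normalization=payload["normalization"],
    )
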