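"""Probabilistic neural network with per-class smoothing factors.

The PNN is a Parzen-window / kernel-density classifier framed as four layers:

* input layer — one unit per feature;
* pattern layer — one Gaussian unit per training sample, centered there,
  with activation ``phi_ij = exp(-||x - X_ij||^2 / sigma_i^2)`` where
  ``sigma_i`` is the smoothing factor of class i (the denominator is
  ``sigma^2``, with no factor 2 — see the methods note);
* summation layer — one unit per class, the arithmetic mean of that class's
  pattern activations (a class-conditional density estimate, equal priors);
* output layer — winner-take-all: the class with the largest summation value
  outputs 1, all others 0.

Class-order ties break toward the first class in ``model.classes`` (the
negative class by construction). Prediction compares densities after a shared
log-domain shift, so the winner is exact even where the literal activations
underflow (e.g. the sigma -> 0 nearest-neighbor limit).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .data_model import ValidationError

__all__ = ["PNNModel", "PNNOutput", "PNNClassifier", "build_pnn",
           "pattern_layer", "summation_layer", "predict", "predict_batch"]

MODEL_FORMAT_VERSION = 1


@dataclass
class PNNModel:
    """Stored training centers grouped by class, plus per-class sigmas."""

    classes: tuple
    centers: list[np.ndarray]   # one (n_i, K) block per class, input order
    sigmas: np.ndarray          # one positive sigma per class
    feature_dim: int

    def __post_init__(self) -> None:
        self.sigmas = np.asarray(self.sigmas, dtype=float)
        if len(self.classes) != len(self.centers) or len(self.classes) != self.sigmas.size:
            raise ValidationError("classes, centers and sigmas must align")
        if np.any(self.sigmas <= 0) or not np.all(np.isfinite(self.sigmas)):
            raise ValidationError("sigmas: must be positive and finite")
        for c, blk in zip(self.classes, self.centers):
            blk = np.asarray(blk, dtype=float)
            if blk.ndim != 2 or blk.shape[0] < 1 or blk.shape[1] != self.feature_dim:
                raise ValidationError(f"class {c}: centers must be (n>=1, {self.feature_dim})")

    @property
    def n_pattern_neurons(self) -> int:
        """Total pattern-layer units — one per training sample."""
        return sum(blk.shape[0] for blk in self.centers)

    @property
    def n_summation_units(self) -> int:
        """Summation-layer units — one per class."""
        return len(self.classes)

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "format_version": MODEL_FORMAT_VERSION,
            "model": "sa-pnn",
            "classes": [int(c) for c in self.classes],
            "sigmas": self.sigmas.tolist(),
            "feature_dim": self.feature_dim,
            "centers": [np.asarray(b).tolist() for b in self.centers],
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PNNModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        doc = json.loads(text)
        if doc.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValidationError(f"unsupported model format version {doc.get('format_version')}")
        return cls(
            classes=tuple(doc["classes"]),
            centers=[np.asarray(b, dtype=float) for b in doc["centers"]],
            sigmas=np.asarray(doc["sigmas"], dtype=float),
            feature_dim=int(doc["feature_dim"]),
        )


@dataclass
class PNNOutput:
    """Layer-by-layer record of a single prediction."""

    pattern_values: list[np.ndarray]   # phi_ij per class, in (0, 1]
    summation_values: np.ndarray       # s_i per class
    predicted_class: int
    output_vector: np.ndarray          # one-hot over classes


def build_pnn(
    train_X: np.ndarray, train_labels: np.ndarray, sigmas: float | Sequence[float]
) -> PNNModel:
    """Build the network from a training set.

    The pattern layer stores every training sample as a center, grouped by
    class in input order; a scalar ``sigmas`` broadcasts to all classes
    (classic single-sigma PNN).
    """
    X = np.asarray(train_X, dtype=float)
    y = np.asarray(train_labels)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValidationError("train_X and train_labels must have matching first dimension")
    classes = tuple(int(c) for c in np.unique(y))
    if len(classes) < 2:
        raise ValidationError("training set must contain both classes")
    sig = np.asarray(sigmas, dtype=float)
    if sig.ndim == 0:
        sig = np.full(len(classes), float(sig))
    if sig.size != len(classes):
        raise ValidationError(f"sigmas: need 1 or {len(classes)} values, got {sig.size}")
    centers = [X[y == c] for c in classes]
    return PNNModel(classes=classes, centers=centers, sigmas=sig, feature_dim=X.shape[1])


def pattern_layer(x: np.ndarray, model: PNNModel) -> list[np.ndarray]:
    """Pattern-layer activations ``exp(-||x - X_ij||^2 / sigma_i^2)`` per class."""
    x = np.asarray(x, dtype=float).reshape(-1)
    if x.size != model.feature_dim:
        raise ValidationError(f"input has {x.size} features, model expects {model.feature_dim}")
    out = []
    for blk, s in zip(model.centers, model.sigmas):
        d2 = np.sum((blk - x) ** 2, axis=1)
        out.append(np.exp(-d2 / s**2))
    return out


def summation_layer(pattern_values: Sequence[np.ndarray]) -> np.ndarray:
    """Per-class mean of pattern activations (neurons of different classes never mix)."""
    if any(len(v) == 0 for v in pattern_values):
        raise ValidationError("summation layer: empty class")
    return np.array([float(np.mean(v)) for v in pattern_values])


def _log_class_scores(model: PNNModel, X: np.ndarray) -> np.ndarray:
    """Stable per-class log mean-kernel scores, (n_samples, n_classes).

    Returns log(s_i) up to a per-row additive constant — sufficient and exact
    for the winner-take-all comparison.
    """
    exps = []
    for blk, s in zip(model.centers, model.sigmas):
        e = -cdist(X, blk, "sqeuclidean") / s**2
        exps.append(e)
    shift = np.max(np.concatenate([e.max(axis=1, keepdims=True) for e in exps], axis=1),
                   axis=1, keepdims=True)
    with np.errstate(divide="ignore"):  # a fully-underflowed class scores -inf
        return np.concatenate(
            [np.log(np.mean(np.exp(e - shift), axis=1, keepdims=True)) for e in exps], axis=1
        )


def predict(model: PNNModel, x: np.ndarray) -> PNNOutput:
    """Classify one sample; winner-take-all over the summation layer."""
    phi = pattern_layer(x, model)
    s = summation_layer(phi)
    scores = _log_class_scores(model, np.asarray(x, dtype=float).reshape(1, -1))[0]
    win = int(np.argmax(scores))  # first max -> first class on ties
    onehot = np.zeros(len(model.classes))
    onehot[win] = 1.0
    return PNNOutput(pattern_values=phi, summation_values=s,
                     predicted_class=model.classes[win], output_vector=onehot)


def predict_batch(model: PNNModel, X: np.ndarray) -> np.ndarray:
    """Vectorized winner-take-all prediction for many samples."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.feature_dim:
        raise ValidationError(f"X must be (n, {model.feature_dim})")
    scores = _log_class_scores(model, X)
    idx = np.argmax(scores, axis=1)
    return np.asarray(model.classes)[idx]


class PNNClassifier:
    """Minimal sklearn-style wrapper around a fixed-sigma PNN.

    Used as the selection classifier in nested subset search and as the
    fixed-sigma / RBF-kernel baseline in the comparison harness.
    """

    def __init__(self, sigma: float | Sequence[float] = 0.1):
        self.sigma = sigma
        self.model_: PNNModel | None = None

    def get_params(self, deep: bool = True) -> dict:
        return {"sigma": self.sigma}

    def fit(self, X: np.ndarray, y: np.ndarray) -> "PNNClassifier":
        self.model_ = build_pnn(X, y, self.sigma)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.model_ is None:
            raise ValidationError("classifier is not fitted")
        return predict_batch(self.model_, X)
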