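"""Synthetic Minority Oversampling Technique (SMOTE).

Rebalances the two classes before training: each synthetic minority sample is
drawn uniformly at random on the line segment between a minority point and one
of its k nearest minority neighbors (Euclidean distance). Majority rows are
never touched and never serve as interpolation endpoints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .data_model import ValidationError

__all__ = ["SmoteConfig", "smote_oversample"]


@dataclass
class SmoteConfig:
    """``target_ratio`` is the minority:majority ratio after oversampling."""

    k_neighbors: int = 5
    target_ratio: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValidationError(f"k_neighbors: must be >= 1, got {self.k_neighbors}")
        if not (0 < self.target_ratio <= 1.0):
            raise ValidationError(f"target_ratio: must be in (0, 1], got {self.target_ratio}")


def synthetic_count(n_minority: int, n_majority: int, target_ratio: float = 1.0) -> int:
    """Number of synthetic samples needed to reach the target class ratio."""
    return max(0, int(round(target_ratio * n_majority)) - n_minority)


def smote_oversample(
    X: np.ndarray, labels: np.ndarray, cfg: SmoteConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Oversample the minority class.

    Returns ``(X_aug, labels_aug, synthetic_flag)``. Original rows are
    unchanged and come first; the boolean flag marks appended synthetic rows.
    Each synthetic sample is ``c + u*(q - c)`` with ``c`` a minority point,
    ``q`` one of its k nearest minority neighbors and ``u ~ Uniform(0,1)``.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != labels.shape[0]:
        raise ValidationError("X and labels must have matching first dimension")
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValidationError("SMOTE requires both classes present")
    if classes.size > 2:
        raise ValidationError("SMOTE supports exactly two classes")
    minority_class = classes[np.argmin(counts)]
    n_min = int(counts.min())
    n_maj = int(counts.max())
    if n_min < 2:
        raise ValidationError("SMOTE needs >= 2 minority samples")

    k = cfg.k_neighbors
    if k > n_min - 1:
        warnings.warn(
            f"k_neighbors={k} exceeds minority size - 1 ({n_min - 1}); clipping",
            stacklevel=2,
        )
        k = n_min - 1

    n_syn = synthetic_count(n_min, n_maj, cfg.target_ratio)
    minority = X[labels == minority_class]

    rng = np.random.default_rng(cfg.seed)
    synth = np.empty((n_syn, X.shape[1]), dtype=float)
    if n_syn > 0:
        # Exact k-NN among minority points only; N is small here.
        d = cdist(minority, minority)
        np.fill_diagonal(d, np.inf)
        nn = np.argsort(d, axis=1, kind="stable")[:, :k]
        centers = rng.integers(0, n_min, size=n_syn)
        picks = rng.integers(0, k, size=n_syn)
        u = rng.random(n_syn)
        c = minority[centers]
        q = minority[nn[centers, picks]]
        synth = c + u[:, None] * (q - c)

    X_aug = np.vstack([X, synth])
    labels_aug = np.concatenate([labels, np.full(n_syn, minority_class, dtype=labels.dtype)])
    flag = np.concatenate([np.zeros(X.shape[0], dtype=bool), np.ones(n_syn, dtype=bool)])
    return X_aug, labels_aug, flag
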