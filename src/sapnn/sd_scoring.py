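"""Statistical Dependency (SD) feature scoring and greedy subset selection.

SD measures whether a discretized feature y depends on the class labels z:

    SD = sum_y sum_z  p(y,z) * p(y,z) / (p(y) * p(z))

with probabilities estimated as empirical relative frequencies. SD = 1 under
independence and grows with dependence; the final per-feature score is SD - 1,
so an uninformative feature scores exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .data_model import (
    FeatureVectorSpec,
    ParamKind,
    SpectralDataset,
    ValidationError,
)

__all__ = [
    "DiscretizationConfig",
    "FeatureScore",
    "discretize",
    "sd_score",
    "score_features",
    "score_all_features",
    "score_matrix",
    "select_feature_subset",
]


@dataclass
class DiscretizationConfig:
    n_bins: int = 10
    strategy: str = "equal_width"

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValidationError(f"n_bins: must be >= 2, got {self.n_bins}")
        if self.strategy != "equal_width":
            raise ValidationError(f"strategy: only 'equal_width' supported, got {self.strategy}")


@dataclass
class FeatureScore:
    frequency_mhz: float
    param_kind: ParamKind
    sd_value: float      # >= 1
    score: float         # sd_value - 1, >= 0
    rank: int            # 1 = most dependent
    column_index: int


def discretize(values: np.ndarray, cfg: DiscretizationConfig) -> np.ndarray:
    """Equal-width binning over [min, max] into ``n_bins`` bins.

    Bins are half-open with the maximum assigned to the last bin; a constant
    vector collapses to bin 0 for every sample.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise ValidationError("values: must be a non-empty 1-D array")
    if not np.all(np.isfinite(v)):
        raise ValidationError("values: contains non-finite entries")
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.zeros(v.size, dtype=np.int64)
    width = (hi - lo) / cfg.n_bins
    bins = np.floor((v - lo) / width).astype(np.int64)
    return np.clip(bins, 0, cfg.n_bins - 1)


def sd_score(y_bins: Sequence[int], z_labels: Sequence) -> float:
    """Statistical dependency between bin labels and class labels.

    Empty contingency cells contribute zero; the value is exactly 1 when the
    bin distribution is identical in every class.
    """
    y = np.asarray(y_bins)
    z = np.asarray(z_labels)
    if y.shape != z.shape or y.ndim != 1:
        raise ValidationError("y_bins and z_labels must be 1-D of equal length")
    if y.size == 0:
        raise ValidationError("empty input")
    n = y.size
    _, yi = np.unique(y, return_inverse=True)
    _, zi = np.unique(z, return_inverse=True)
    joint = np.zeros((yi.max() + 1, zi.max() + 1), dtype=float)
    np.add.at(joint, (yi, zi), 1.0)
    p = joint / n
    py = p.sum(axis=1, keepdims=True)
    pz = p.sum(axis=0, keepdims=True)
    mask = p > 0
    return float(np.sum(p[mask] ** 2 / (py * pz)[mask]))


def score_matrix(
    X: np.ndarray, labels: np.ndarray, disc: DiscretizationConfig
) -> np.ndarray:
    """Per-column SD values for a plain feature matrix."""
    X = np.asarray(X, dtype=float)
    return np.array([sd_score(discretize(X[:, j], disc), labels) for j in range(X.shape[1])])


def score_features(
    X: np.ndarray,
    labels: np.ndarray,
    frequencies_mhz: np.ndarray,
    param_kind: ParamKind,
    disc: DiscretizationConfig,
) -> list[FeatureScore]:
    """Score each column of a feature matrix; ranked by score descending.

    Ties are broken by the lower frequency, so the ranking is deterministic.
    Accepts a plain matrix so SMOTE-augmented training data can be scored.
    """
    freqs = np.asarray(frequencies_mhz, dtype=float)
    sd = score_matrix(X, labels, disc)
    order = sorted(range(len(sd)), key=lambda j: (-(sd[j] - 1.0), freqs[j]))
    return [
        FeatureScore(
            frequency_mhz=float(freqs[j]),
            param_kind=ParamKind(param_kind),
            sd_value=float(sd[j]),
            score=float(sd[j] - 1.0),
            rank=r + 1,
            column_index=j,
        )
        for r, j in enumerate(order)
    ]


def score_all_features(
    ds: SpectralDataset, disc: DiscretizationConfig
) -> list[FeatureScore]:
    """Score every frequency column of a dataset (see :func:`score_features`)."""
    return score_features(ds.features, ds.labels, ds.grid.points, ds.param_kind, disc)


def select_feature_subset(
    scores: Sequence[FeatureScore],
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    classifier_factory: Callable[[], object],
    k_max: int = 20,
) -> FeatureVectorSpec:
    """Pick the best nested top-k subset along the SD ranking.

    For k = 1..k_max the top-k ranked frequencies are used to train a fresh
    classifier from ``classifier_factory`` on the training rows; the subset
    with the highest validation accuracy wins, ties going to the smaller k.
    ``X_train``/``X_val`` are full-width matrices whose columns correspond to
    the scores' ``column_index``.
    """
    if k_max < 1:
        raise ValidationError(f"k_max: must be >= 1, got {k_max}")
    ranked = sorted(scores, key=lambda s: s.rank)
    p = len(ranked)
    if k_max > p:
        import warnings

        warnings.warn(f"k_max={k_max} exceeds feature count {p}; clipping", stacklevel=2)
        k_max = p
    best_k, best_acc = 1, -1.0
    for k in range(1, k_max + 1):
        cols = [s.column_index for s in ranked[:k]]
        clf = classifier_factory()
        clf.fit(X_train[:, cols], y_train)
        acc = float(np.mean(np.asarray(clf.predict(X_val[:, cols])) == np.asarray(y_val)))
        if acc > best_acc:
            best_k, best_acc = k, acc
    chosen = ranked[:best_k]
    spec = FeatureVectorSpec(
        param_kind=chosen[0].param_kind,
        frequencies_mhz=[s.frequency_mhz for s in chosen],
        column_indices=[s.column_index for s in chosen],
    )
    return spec
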