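"""Stratified splitting, repeated hold-out evaluation, and baselines.

The protocol is Monte-Carlo cross-validation: per repeat, a stratified
60/20/20 train/validation/test split (a fresh seed each repeat), the pipeline
fit on train (validation reserved for model selection / the annealer's
overfit guard), and sensitivity / specificity / accuracy measured on the
untouched test set. Metrics are averaged over the repeats (20 by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .data_model import ClassLabel, ValidationError
from .pnn import PNNClassifier
from .smote import SmoteConfig, smote_oversample

__all__ = [
    "SplitSpec",
    "ConfusionCounts",
    "EvaluationReport",
    "stratified_split",
    "confusion",
    "metrics",
    "repeat_holdout",
    "make_classifier",
    "compare_classifiers",
]


@dataclass
class SplitSpec:
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)  # train, val, test
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        f = self.fractions
        if len(f) != 3 or any(not (0 < x < 1) for x in f):
            raise ValidationError(f"fractions: each must be in (0,1), got {f}")
        if abs(sum(f) - 1.0) > 1e-9:
            raise ValidationError(f"fractions: must sum to 1, got {sum(f)}")


@dataclass
class ConfusionCounts:
    """TP/FN count the positive (tumor) class; TN/FP the negative class."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


@dataclass
class EvaluationReport:
    """Per-repeat (ACC, SEN, SPE) triples in percent, plus their means."""

    classifier: str
    params: dict
    per_repeat: list[tuple[float, float, float]]  # (acc, sen, spe)

    @property
    def mean_acc(self) -> float:
        return float(np.mean([r[0] for r in self.per_repeat]))

    @property
    def mean_sen(self) -> float:
        return float(np.mean([r[1] for r in self.per_repeat]))

    @property
    def mean_spe(self) -> float:
        return float(np.mean([r[2] for r in self.per_repeat]))

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"classifier": self.classifier, "params": repr(self.params), "repeat": i + 1,
             "acc": a, "sen": s, "spe": p}
            for i, (a, s, p) in enumerate(self.per_repeat)
        ]
        return pd.DataFrame(rows)


def stratified_split(
    labels: np.ndarray, spec: SplitSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stratified train/validation/test index sets.

    Within each class, floor(fraction * n_class) samples go to validation and
    test; the remainder (the slack) goes to training. Indices are disjoint and
    exhaustive; the shuffle is driven by ``spec.seed``.
    """
    y = np.asarray(labels)
    rng = np.random.default_rng(spec.seed)
    _, f_val, f_test = spec.fractions
    train, val, test = [], [], []
    for c in np.unique(y):
        idx = np.nonzero(y == c)[0]
        if idx.size < 3:
            raise ValidationError(f"class {c}: needs >= 3 samples, has {idx.size}")
        if spec.stratified:
            idx = rng.permutation(idx)
        n_val = int(np.floor(f_val * idx.size))
        n_test = int(np.floor(f_test * idx.size))
        val.append(idx[:n_val])
        test.append(idx[n_val:n_val + n_test])
        train.append(idx[n_val + n_test:])
    return (np.sort(np.concatenate(train)), np.sort(np.concatenate(val)),
            np.sort(np.concatenate(test)))


def confusion(
    pred: Sequence, truth: Sequence, positive_class=ClassLabel.POSITIVE
) -> ConfusionCounts:
    """Confusion counts with the metastatic/tumor class as positive."""
    p = np.asarray(pred)
    t = np.asarray(truth)
    if p.shape != t.shape:
        raise ValidationError("pred and truth must have equal length")
    valid = {int(ClassLabel.NEGATIVE), int(ClassLabel.POSITIVE)}
    if not set(np.unique(p)).issubset(valid) or not set(np.unique(t)).issubset(valid):
        raise ValidationError("labels outside the two declared classes")
    pos = t == positive_class
    pred_pos = p == positive_class
    return ConfusionCounts(
        tp=int(np.sum(pos & pred_pos)),
        fn=int(np.sum(pos & ~pred_pos)),
        tn=int(np.sum(~pos & ~pred_pos)),
        fp=int(np.sum(~pos & pred_pos)),
    )


def metrics(cc: ConfusionCounts) -> tuple[float, float, float]:
    """(SEN, SPE, ACC) in percent.

    SEN = TP/(TP+FN), SPE = TN/(FP+TN), ACC = (TP+TN)/total, each x 100.
    An undefined metric (empty class in the evaluated set) is returned as NaN
    with a warning.
    """
    if cc.total == 0:
        raise ValidationError("all-zero confusion counts")
    if cc.tp + cc.fn > 0:
        sen = 100.0 * cc.tp / (cc.tp + cc.fn)
    else:
        warnings.warn("no positive samples in evaluated set; SEN undefined", stacklevel=2)
        sen = float("nan")
    if cc.tn + cc.fp > 0:
        spe = 100.0 * cc.tn / (cc.fp + cc.tn)
    else:
        warnings.warn("no negative samples in evaluated set; SPE undefined", stacklevel=2)
        spe = float("nan")
    acc = 100.0 * (cc.tp + cc.tn) / cc.total
    return sen, spe, acc


def repeat_holdout(
    features: np.ndarray,
    labels: np.ndarray,
    pipeline: Callable[[np.ndarray, np.ndarray, int], ConfusionCounts],
    n_repeats: int = 20,
    base_seed: int = 0,
    classifier: str = "pipeline",
    params: dict | None = None,
) -> EvaluationReport:
    """Repeat-averaged hold-out evaluation.

    ``pipeline(features, labels, seed)`` must perform its own split with the
    given seed, fit, and return test-set confusion counts; repeat r uses seed
    ``base_seed + r``.
    """
    per_repeat = []
    for r in range(n_repeats):
        cc = pipeline(features, labels, base_seed + r)
        sen, spe, acc = metrics(cc)
        per_repeat.append((acc, sen, spe))
    return EvaluationReport(classifier=classifier, params=params or {}, per_repeat=per_repeat)


def make_classifier(name: str, **params):
    """Baseline comparator factory (thin adapters over scikit-learn).

    Ids: ``pnn`` (fixed sigma), ``rbf`` (shared-sigma Gaussian-kernel density
    classifier, same machinery), ``knn``, ``svm`` (kernel name), ``classify``
    (discriminant type: linear/quadratic/diaglinear/diagquadratic), ``bp``
    (one-hidden-layer perceptron, hidden unit count).
    """
    name = name.lower()
    if name in ("pnn", "rbf"):
        return PNNClassifier(sigma=params.get("sigma", 0.1))
    if name == "knn":
        from sklearn.neighbors import KNeighborsClassifier

        return KNeighborsClassifier(n_neighbors=params.get("k", 1))
    if name == "svm":
        from sklearn.svm import SVC

        kernel = params.get("kernel", "rbf")
        if kernel == "quadratic":
            return SVC(kernel="poly", degree=2)
        return SVC(kernel=kernel)
    if name == "classify":
        kind = params.get("type", "linear")
        if kind == "linear":
            from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

            return LinearDiscriminantAnalysis()
        if kind == "quadratic":
            from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis

            return QuadraticDiscriminantAnalysis()
        if kind in ("diaglinear", "diagquadratic"):
            from sklearn.naive_bayes import GaussianNB

            return GaussianNB()
        raise ValidationError(f"unknown classify type '{kind}'")
    if name == "bp":
        from sklearn.neural_network import MLPClassifier

        return MLPClassifier(
            hidden_layer_sizes=(params.get("hidden", 10),),
            max_iter=params.get("max_iter", 500),
            random_state=params.get("random_state", 0),
        )
    raise ValidationError(f"unknown classifier id '{name}'")


def _fit_eval_pipeline(name: str, params: dict, split: SplitSpec, smote_cfg: SmoteConfig | None):
    """Split -> SMOTE(train) -> fit -> test confusion, for one baseline."""

    def run(X: np.ndarray, y: np.ndarray, seed: int) -> ConfusionCounts:
        sp = SplitSpec(fractions=split.fractions, stratified=split.stratified, seed=seed)
        tr, va, te = stratified_split(y, sp)
        Xtr, ytr = X[tr], y[tr]
        if smote_cfg is not None:
            cfg = SmoteConfig(k_neighbors=smote_cfg.k_neighbors,
                              target_ratio=smote_cfg.target_ratio, seed=seed)
            Xtr, ytr, _ = smote_oversample(Xtr, ytr, cfg)
        clf = make_classifier(name, **params)
        clf.fit(Xtr, ytr)
        return confusion(clf.predict(X[te]), y[te])

    return run


def compare_classifiers(
    features: np.ndarray,
    labels: np.ndarray,
    sweep: dict[str, list[dict]],
    n_repeats: int = 20,
    base_seed: int = 0,
    split: SplitSpec | None = None,
    smote_cfg: SmoteConfig | None = None,
) -> pd.DataFrame:
    """Hyperparameter sweep over baseline classifiers.

    ``sweep`` maps a classifier id to a list of parameter dicts. Returns one
    row per (classifier, params) with repeat-mean metrics; the best row per
    classifier (by mean accuracy) is flagged in the ``best`` column.
    """
    split = split or SplitSpec()
    rows = []
    for name, grid in sweep.items():
        for params in grid:
            rep = repeat_holdout(
                features, labels, _fit_eval_pipeline(name, params, split, smote_cfg),
                n_repeats=n_repeats, base_seed=base_seed, classifier=name, params=params,
            )
            rows.append({"classifier": name, "params": repr(params),
                         "mean_acc": rep.mean_acc, "mean_sen": rep.mean_sen,
                         "mean_spe": rep.mean_spe})
    df = pd.DataFrame(rows)
    df["best"] = False
    for name in df["classifier"].unique():
        sub = df[df["classifier"] == name]
        df.loc[sub["mean_acc"].idxmax(), "best"] = True
    return df
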