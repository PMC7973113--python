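"""Stratified splitting, confusion metrics and the hold-out harness."""

import numpy as np
import pytest

from sapnn import (
    ConfusionCounts,
    SmoteConfig,
    SplitSpec,
    ValidationError,
    compare_classifiers,
    confusion,
    metrics,
    repeat_holdout,
    stratified_split,
)
from sapnn.evaluation import make_classifier

from conftest import separable_benchmark


class TestStratifiedSplit:
    def test_exact_divisibility_per_class(self):
        y = np.array([0] * 100 + [1] * 100)
        tr, va, te = stratified_split(y, SplitSpec(seed=0))
        assert (len(tr), len(va), len(te)) == (120, 40, 40)
        for part in (tr, va, te):
            counts = np.bincount(y[part], minlength=2)
            assert counts[0] == counts[1]

    def test_cohort_counts_floor_arithmetic(self):
        # 41 positive / 178 negative: floors 8/35 to val and test, slack to train
        y = np.array([1] * 41 + [0] * 178)
        tr, va, te = stratified_split(y, SplitSpec(seed=3))
        assert np.bincount(y[va], minlength=2).tolist() == [35, 8]
        assert np.bincount(y[te], minlength=2).tolist() == [35, 8]
        assert np.bincount(y[tr], minlength=2).tolist() == [108, 25]

    def test_partition_disjoint_and_exhaustive(self):
        y = np.array([0] * 37 + [1] * 13)
        tr, va, te = stratified_split(y, SplitSpec(seed=5))
        all_idx = np.concatenate([tr, va, te])
        assert len(set(all_idx.tolist())) == len(y)
        assert sorted(all_idx.tolist()) == list(range(len(y)))

    def test_same_seed_identical_partition(self):
        y = np.array([0] * 30 + [1] * 10)
        a = stratified_split(y, SplitSpec(seed=9))
        b = stratified_split(y, SplitSpec(seed=9))
        for u, v in zip(a, b):
            np.testing.assert_array_equal(u, v)

    def test_tiny_class_rejected(self):
        y = np.array([0] * 10 + [1] * 2)
        with pytest.raises(ValidationError, match="class 1"):
            stratified_split(y, SplitSpec(seed=0))


class TestConfusionAndMetrics:
    def test_perfect_classifier(self):
        cc = confusion([1] * 5 + [0] * 5, [1] * 5 + [0] * 5)
        assert (cc.tp, cc.fn, cc.tn, cc.fp) == (5, 0, 5, 0)
        assert metrics(cc) == (100.0, 100.0, 100.0)

    def test_fully_inverted_classifier(self):
        cc = confusion([0] * 5 + [1] * 5, [1] * 5 + [0] * 5)
        assert (cc.tp, cc.fn, cc.tn, cc.fp) == (0, 5, 0, 5)

    def test_all_positive_prediction_counts(self):
        cc = confusion([1] * 10, [1] * 3 + [0] * 7)
        assert (cc.tp, cc.fn, cc.tn, cc.fp) == (3, 0, 0, 7)

    def test_hand_evaluated_formulas(self):
        sen, spe, acc = metrics(ConfusionCounts(tp=3, fn=1, tn=4, fp=2))
        assert sen == pytest.approx(75.0)
        assert spe == pytest.approx(100 * 4 / 6)
        assert acc == pytest.approx(70.0)

    def test_one_sided_failure(self):
        sen, spe, acc = metrics(ConfusionCounts(tp=0, fn=5, tn=5, fp=0))
        assert (sen, spe, acc) == (0.0, 100.0, 50.0)

    def test_accuracy_is_prevalence_weighted_combination(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            tp, fn, tn, fp = rng.integers(1, 30, 4)
            cc = ConfusionCounts(int(tp), int(fn), int(tn), int(fp))
            sen, spe, acc = metrics(cc)
            expect = (sen * (cc.tp + cc.fn) + spe * (cc.tn + cc.fp)) / cc.total
            assert acc == pytest.approx(expect, abs=1e-9)

    def test_label_outside_classes_rejected(self):
        with pytest.raises(ValidationError):
            confusion([2, 0], [1, 0])

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValidationError):
            metrics(ConfusionCounts(0, 0, 0, 0))


class TestRepeatHoldout:
    @staticmethod
    def _const_pipeline(X, y, seed):
        # seed-independent confusion: simulates a deterministic classifier
        return ConfusionCounts(tp=3, fn=1, tn=4, fp=2)

    def test_deterministic_pipeline_aggregation_identity(self):
        X, y = separable_benchmark(0, n_per_class=10)
        rep = repeat_holdout(X, y, self._const_pipeline, n_repeats=20, base_seed=0)
        assert len(rep.per_repeat) == 20
        assert len(set(rep.per_repeat)) == 1
        sen, spe, acc = metrics(ConfusionCounts(3, 1, 4, 2))
        assert rep.mean_acc == pytest.approx(acc)
        assert rep.mean_sen == pytest.approx(sen)
        assert rep.mean_spe == pytest.approx(spe)

    def test_single_repeat_equals_single_run(self):
        X, y = separable_benchmark(0, n_per_class=10)
        rep = repeat_holdout(X, y, self._const_pipeline, n_repeats=1, base_seed=0)
        assert len(rep.per_repeat) == 1
        assert rep.mean_acc == rep.per_repeat[0][0]


class TestCompareClassifiers:
    def test_sweep_accounting_and_best_flag(self):
        X, y = separable_benchmark(0, n_per_class=30)
        df = compare_classifiers(X, y, {"pnn": [{"sigma": 0.05}, {"sigma": 0.1},
                                                {"sigma": 0.2}]},
                                 n_repeats=3, base_seed=0, smote_cfg=None)
        assert len(df) == 3
        assert df["best"].sum() == 1
        assert df.loc[df["best"], "mean_acc"].iloc[0] == df["mean_acc"].max()

    def test_knn_k1_memorizes_its_training_set(self):
        X, y = separable_benchmark(1, n_per_class=15)
        clf = make_classifier("knn", k=1)
        clf.fit(X, y)
        assert np.mean(clf.predict(X) == y) == 1.0

    def test_unknown_classifier_id_rejected(self):
        with pytest.raises(ValidationError, match="unknown classifier"):
            make_classifier("forest")

    def test_sa_pnn_not_worse_than_best_fixed_sigma_grid(self):
        """The anneal searches a superset of any fixed-sigma grid; on paired
        splits its mean accuracy should be within one point of the grid's."""
        from sapnn.evaluation import _fit_eval_pipeline
        from sapnn.sa_optimizer import SAConfig, optimize_sigma
        from sapnn.pnn import build_pnn, predict_batch

        X, y = separable_benchmark(2, n_per_class=40)
        n_rep, base_seed = 5, 10
        split = SplitSpec()

        grid_accs = []
        for sigma in (0.05, 0.1, 0.5, 1.0, 2.0):
            rep = repeat_holdout(X, y, _fit_eval_pipeline("pnn", {"sigma": sigma},
                                                          split, None),
                                 n_repeats=n_rep, base_seed=base_seed)
            grid_accs.append(rep.mean_acc)

        def sa_pipeline(Xa, ya, seed):
            tr, va, te = stratified_split(ya, SplitSpec(seed=seed))
            cfg = SAConfig(t0=10.0, alpha=0.8, count_per_temp=25, t_min=0.05,
                           max_restarts=1, seed=seed)
            res = optimize_sigma(Xa[tr], ya[tr], Xa[va], ya[va], cfg)
            model = build_pnn(Xa[tr], ya[tr], res.best_sigma)
            return confusion(predict_batch(model, Xa[te]), ya[te])

        sa_rep = repeat_holdout(X, y, sa_pipeline, n_repeats=n_rep, base_seed=base_seed)
        assert sa_rep.mean_acc >= max(grid_accs) - 1.0
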