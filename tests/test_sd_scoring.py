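"""Statistical-dependency scoring: binning, the SD statistic, ranking,
nested subset selection — checked against a brute-force contingency oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sapnn import (
    ClassLabel,
    DiscretizationConfig,
    ParamKind,
    SpectralDataset,
    ValidationError,
    discretize,
    make_uniform_grid,
    score_all_features,
    score_features,
    sd_score,
    select_feature_subset,
)
from sapnn.pnn import PNNClassifier

from conftest import sd_brute_force


class TestDiscretize:
    def test_boundary_goes_to_upper_bin(self):
        bins = discretize(np.array([0.0, 0.5, 1.0]), DiscretizationConfig(n_bins=2))
        assert bins.tolist() == [0, 1, 1]

    def test_constant_vector_collapses_to_bin_zero(self):
        bins = discretize(np.full(7, 3.14), DiscretizationConfig(n_bins=10))
        assert bins.tolist() == [0] * 7

    def test_one_to_ten_fills_all_ten_bins(self):
        bins = discretize(np.arange(1.0, 11.0), DiscretizationConfig(n_bins=10))
        assert bins.tolist() == list(range(10))

    def test_non_finite_rejected(self):
        with pytest.raises(ValidationError, match="non-finite"):
            discretize(np.array([1.0, np.nan]), DiscretizationConfig())


class TestSdScore:
    def test_independence_floor_is_exactly_one(self):
        # identical bin distribution in both classes
        assert sd_score([0, 1, 0, 1], ["A", "A", "B", "B"]) == 1.0

    def test_perfect_balanced_dependence_is_two(self):
        assert sd_score([0, 0, 1, 1], ["A", "A", "B", "B"]) == pytest.approx(2.0, abs=1e-15)

    def test_single_sample_is_one(self):
        assert sd_score([3], ["A"]) == 1.0

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            sd_score([0, 1], ["A"])

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_brute_force_contingency(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 40))
        y = rng.integers(0, 5, n)
        z = rng.integers(0, 2, n)
        if len(set(z.tolist())) < 2:
            z[0] = 1 - z[0]
        assert sd_score(y, z) == pytest.approx(sd_brute_force(y, z), abs=1e-12)

    @given(st.lists(st.tuples(st.integers(0, 4), st.integers(0, 1)), min_size=1, max_size=60))
    @settings(max_examples=60, derandomize=True)
    def test_sd_at_least_one(self, pairs):
        y = [a for a, _ in pairs]
        z = [b for _, b in pairs]
        assert sd_score(y, z) >= 1.0 - 1e-12

    def test_invariant_under_relabeling(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 4, 50)
        z = rng.integers(0, 2, 50)
        base = sd_score(y, z)
        perm = np.array([2, 0, 3, 1])
        assert sd_score(perm[y], z) == pytest.approx(base, abs=1e-12)
        assert sd_score(y, 1 - z) == pytest.approx(base, abs=1e-12)

    def test_invariant_under_dataset_duplication(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 3, 30)
        z = rng.integers(0, 2, 30)
        assert sd_score(np.r_[y, y], np.r_[z, z]) == pytest.approx(sd_score(y, z), abs=1e-12)


class TestScoreAllFeatures:
    def test_perfect_predictor_column_ranks_first(self):
        rng = np.random.default_rng(0)
        grid = make_uniform_grid(100, 1000, 100)
        labels = rng.integers(0, 2, 60)
        feats = rng.normal(size=(60, grid.n_points))
        feats[:, 4] = labels.astype(float)  # the label itself, at 500 MHz
        ds = SpectralDataset(features=feats, grid=grid, param_kind="conductivity",
                             labels=labels, sample_ids=[f"s{i}" for i in range(60)])
        scores = score_all_features(ds, DiscretizationConfig(n_bins=5))
        assert scores[0].column_index == 4
        assert scores[0].frequency_mhz == 500
        # brute-force cross-check of the winning score
        from sapnn.sd_scoring import discretize as disc

        expect = sd_brute_force(disc(feats[:, 4], DiscretizationConfig(n_bins=5)), labels)
        assert scores[0].sd_value == pytest.approx(expect, abs=1e-12)

    def test_all_constant_dataset_scores_zero_everywhere(self):
        grid = make_uniform_grid(100, 400, 100)
        ds = SpectralDataset(features=np.ones((10, 4)), grid=grid,
                             param_kind="conductivity",
                             labels=np.array([0] * 5 + [1] * 5),
                             sample_ids=[f"s{i}" for i in range(10)])
        scores = score_all_features(ds, DiscretizationConfig())
        assert all(s.score == 0.0 and s.sd_value == 1.0 for s in scores)

    def test_ranks_are_permutation_and_ties_break_low_frequency(self):
        grid = make_uniform_grid(100, 400, 100)
        ds = SpectralDataset(features=np.ones((10, 4)), grid=grid,
                             param_kind="conductivity",
                             labels=np.array([0] * 5 + [1] * 5),
                             sample_ids=[f"s{i}" for i in range(10)])
        scores = score_all_features(ds, DiscretizationConfig())
        assert [s.rank for s in scores] == [1, 2, 3, 4]
        assert [s.frequency_mhz for s in scores] == [100, 200, 300, 400]


class _MajorityDummy:
    def fit(self, X, y):
        vals, counts = np.unique(y, return_counts=True)
        self.c_ = vals[np.argmax(counts)]
        return self

    def predict(self, X):
        return np.full(len(X), self.c_)


class TestSelectFeatureSubset:
    def _scores(self, X, y, grid):
        return score_features(X, y, grid.points, ParamKind.CONDUCTIVITY,
                              DiscretizationConfig(n_bins=5))

    def test_majority_dummy_ties_resolve_to_k_equals_one(self):
        rng = np.random.default_rng(0)
        grid = make_uniform_grid(100, 600, 100)
        X = rng.normal(size=(40, 6))
        y = np.array([0] * 25 + [1] * 15)
        spec = select_feature_subset(self._scores(X, y, grid), X, y, X, y,
                                     _MajorityDummy, k_max=6)
        assert len(spec.frequencies_mhz) == 1

    def test_two_complementary_informative_columns_selected(self):
        # class 1 splits into two groups, each visible in exactly one column;
        # one column alone misses half the positives, two catch them all
        rng = np.random.default_rng(3)
        n = 80
        y = np.array([0] * 40 + [1] * 40)
        grid = make_uniform_grid(100, 500, 100)
        X = rng.normal(0, 0.05, size=(n, 5))
        X[40:60, 0] += 3.0
        X[60:80, 1] += 3.0
        tr = np.r_[0:30, 40:55, 60:75]
        va = np.r_[30:40, 55:60, 75:80]
        spec = select_feature_subset(self._scores(X[tr], y[tr], grid),
                                     X[tr], y[tr], X[va], y[va],
                                     lambda: PNNClassifier(sigma=0.5), k_max=5)
        assert len(spec.frequencies_mhz) == 2
        assert set(spec.column_indices) == {0, 1}

    def test_k_max_clipped_to_feature_count(self):
        rng = np.random.default_rng(1)
        grid = make_uniform_grid(100, 300, 100)
        X = rng.normal(size=(30, 3))
        y = np.array([0] * 15 + [1] * 15)
        with pytest.warns(UserWarning, match="clipping"):
            spec = select_feature_subset(self._scores(X, y, grid), X, y, X, y,
                                         _MajorityDummy, k_max=99)
        assert len(spec.frequencies_mhz) <= 3
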