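"""Benchmark protocol: discretization, splits, trend fits, model selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from benthoscape.bench import (
    binned_trend,
    equal_width_discretize,
    inverse_trend_fit,
    roc_and_confusion,
    select_model,
    split_train_test,
    sweep,
)


class TestDiscretize:
    def test_unit_interval_terciles(self):
        disc = equal_width_discretize(np.array([0.1, 0.5, 0.9]), 3, (0.0, 1.0))
        assert disc.edges[1] == pytest.approx(1 / 3)
        assert disc.edges[2] == pytest.approx(2 / 3)
        assert list(disc.labels) == [0, 1, 2]

    def test_two_class_cut_at_midpoint(self):
        disc = equal_width_discretize(np.array([1.0, 9.0]), 2, (0.0, 10.0))
        assert disc.edges[1] == pytest.approx(5.0)

    def test_right_open_intervals_except_last(self):
        disc = equal_width_discretize(np.array([0.0, 1 / 3, 2 / 3, 1.0]), 3, (0.0, 1.0))
        assert list(disc.labels) == [0, 1, 2, 2]

    def test_constant_response_rejected(self):
        with pytest.raises(ValueError):
            equal_width_discretize(np.full(10, 3.0), 4)

    @given(st.lists(st.floats(0, 1), min_size=5, max_size=40), st.integers(2, 10))
    @settings(max_examples=50, deadline=None)
    def test_partition_property(self, values, k):
        disc = equal_width_discretize(np.array(values), k, (0.0, 1.0))
        assert disc.labels.min() >= 0 and disc.labels.max() <= k - 1
        assert len(disc.labels) == len(values)
        counts = np.bincount(disc.labels, minlength=k)
        assert counts.sum() == len(values)


class TestSplit:
    def test_300_stations_split_200_100(self):
        train, test = split_train_test(300, test_n=100, seed=0)
        assert len(train) == 200 and len(test) == 100
        assert not set(train) & set(test)
        assert sorted(set(train) | set(test)) == list(range(300))

    def test_same_seed_identical(self):
        a = split_train_test(120, 40, seed=9)
        b = split_train_test(120, 40, seed=9)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_bad_test_size_rejected(self):
        with pytest.raises(ValueError):
            split_train_test(50, 50)


class TestInverseTrend:
    def test_exact_inverse_series_r2adj_one(self):
        ks = np.arange(2, 11)
        fit = inverse_trend_fit(ks, 0.3 + 1.2 / ks)
        assert fit.r2_adj == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.3)
        assert fit.slope == pytest.approx(1.2)

    def test_constant_series_r2adj_minus_one_seventh(self):
        ks = np.arange(2, 11)
        fit = inverse_trend_fit(ks, np.full(9, 0.5))
        assert fit.r2 == pytest.approx(0.0, abs=1e-12)
        assert fit.r2_adj == pytest.approx(-1 / 7)

    def test_coefficients_match_normal_equations(self, rng):
        ks = np.arange(2, 11)
        y = rng.uniform(0, 1, 9)
        A = np.column_stack([np.ones(9), 1.0 / ks])
        expected = np.linalg.solve(A.T @ A, A.T @ y)
        fit = inverse_trend_fit(ks, y)
        assert fit.intercept == pytest.approx(expected[0], rel=1e-9)
        assert fit.slope == pytest.approx(expected[1], rel=1e-9)


def _cube(rows):
    return pd.DataFrame(rows, columns=["response", "learner", "k", "CA", "AUC", "IS", "Bs"])


class TestSelectModel:
    def test_dominant_cell_selected_and_binary_excluded(self):
        cube = _cube([
            ("D", "svm", 2, 0.99, 0.9, 0.5, 0.1),   # excluded: binary
            ("D", "random_forest", 3, 0.7, 0.8, 0.5, 0.2),
            ("A", "naive_bayes", 4, 0.6, 0.8, 0.5, 0.3),
        ])
        assert select_model(cube) == ("D", "random_forest", 3)

    def test_ca_tie_broken_by_lower_brier(self):
        cube = _cube([
            ("D", "svm", 3, 0.7, 0.8, 0.5, 0.30),
            ("D", "random_forest", 3, 0.7, 0.8, 0.5, 0.20),
        ])
        assert select_model(cube) == ("D", "random_forest", 3)

    def test_ca_takes_precedence_over_brier(self):
        cube = _cube([
            ("D", "svm", 3, 0.75, 0.8, 0.5, 0.40),
            ("D", "random_forest", 3, 0.70, 0.8, 0.5, 0.10),
        ])
        assert select_model(cube) == ("D", "svm", 3)

    def test_full_tie_broken_by_learner_order(self):
        cube = _cube([
            ("D", "cn2", 3, 0.7, 0.8, 0.5, 0.2),
            ("D", "naive_bayes", 3, 0.7, 0.8, 0.5, 0.2),
        ])
        assert select_model(cube) == ("D", "naive_bayes", 3)


class TestRocAndConfusion:
    def test_six_point_staircase_matches_hand_enumeration(self):
        scores = np.array([0.9, 0.8, 0.7, 0.6, 0.4, 0.2])
        y = np.array([1, 1, 0, 1, 0, 0])
        P = np.column_stack([1 - scores, scores])
        out = roc_and_confusion(P, y, 2)
        fpr, tpr = out["roc"][1]["fpr"], out["roc"][1]["tpr"]
        points = set(zip(np.round(fpr, 9), np.round(tpr, 9)))
        expected = {(0, 0), (0, 1 / 3), (0, 2 / 3), (1 / 3, 2 / 3),
                    (1 / 3, 1.0), (1.0, 1.0)}
        assert {(round(a, 9), round(b, 9)) for a, b in expected} <= points
        # the equal-cost optimum attains max(TPR - FPR) = 2/3, reached at
        # either (0, 2/3) or (1/3, 1)
        f, t = out["roc"][1]["optimal_point"]
        assert t - f == pytest.approx(2 / 3)
        assert (round(f, 9), round(t, 9)) in {(0.0, round(2 / 3, 9)), (round(1 / 3, 9), 1.0)}

    def test_perfect_scores_pass_through_corner(self):
        y = np.array([0, 0, 1, 1])
        P = np.eye(2)[y]
        out = roc_and_confusion(P, y, 2)
        assert (0.0, 1.0) in set(zip(out["roc"][1]["fpr"], out["roc"][1]["tpr"]))
        assert np.trace(out["confusion"]) == 4

    def test_confusion_proportions(self):
        y = np.array([0, 0, 1, 1, 2, 2])
        pred = np.array([0, 1, 1, 1, 2, 0])
        P = np.eye(3)[pred]
        out = roc_and_confusion(P, y, 3)
        assert out["confusion"].sum() == 6
        assert out["true_proportions"][1] == pytest.approx(1.0)
        assert out["predicted_proportions"][1] == pytest.approx(2 / 3)


class TestBinnedTrend:
    def test_linear_data_degree2_r2_one(self):
        x = np.linspace(0, 10, 60)
        out = binned_trend(2 * x + 1, x, bin_size=20, model="poly2")
        assert out["r2"] == pytest.approx(1.0)

    def test_bin_count_is_floor_n_over_binsize(self):
        x = np.arange(65.0)
        out = binned_trend(x, x, bin_size=20)
        assert len(out["bin_response"]) == 3

    def test_block_means_match_brute_force(self, rng):
        x = rng.uniform(0, 1, 60)
        y = rng.uniform(0, 1, 60)
        out = binned_trend(y, x, bin_size=20)
        order = np.argsort(x, kind="stable")
        for b in range(3):
            block = order[b * 20 : (b + 1) * 20]
            assert out["bin_response"][b] == pytest.approx(y[block].mean(), rel=1e-12)
            assert out["bin_predictor"][b] == pytest.approx(x[block].mean(), rel=1e-12)


class TestSweep:
    def test_small_sweep_structure_and_failure_logging(self, rng):
        X = pd.DataFrame(rng.normal(0, 1, (60, 3)), columns=["a", "b", "c"])
        resp = pd.DataFrame({
            "D": X["a"].to_numpy() + 0.1 * rng.normal(size=60),
            "flat": np.full(60, 2.0),  # constant: every cell must fail gracefully
        })
        cube = sweep(X, resp, learners=("naive_bayes", "c45"), ks=(2, 3), test_n=20, seed=0)
        assert len(cube) == 2 * 2 * 2
        good = cube[cube["response"] == "D"]
        assert good["CA"].between(0, 1).all()
        assert cube[cube["response"] == "flat"]["CA"].isna().all()
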