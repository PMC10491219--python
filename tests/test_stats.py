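"""Binning, derivatives, dissimilarity, rank-sum tests, percent positive."""

import itertools

import numpy as np
import pandas as pd
import pytest

import cytolineage as cl
from cytolineage.stats import StatsError, _wilcoxon_rank_sum


class TestBinning:
    def test_exact_division(self):
        rng = np.random.default_rng(0)
        pt = rng.random(1000)
        X = rng.random((1000, 3))
        binned = cl.bin_pseudotime(pt, X, ["a", "b", "c"], n_bins=200)
        assert (binned.counts == 5).all()
        assert np.all(np.diff(binned.midpoints) >= 0)

    def test_remainder_water_fill(self):
        rng = np.random.default_rng(1)
        binned = cl.bin_pseudotime(rng.random(1003), rng.random((1003, 1)),
                                   ["m"], n_bins=200)
        assert binned.counts[:3].tolist() == [6, 6, 6]
        assert (binned.counts[3:] == 5).all()

    def test_constant_marker_constant_means(self):
        pt = np.linspace(0, 1, 400)
        X = np.full((400, 1), 2.5)
        binned = cl.bin_pseudotime(pt, X, ["m"], n_bins=40)
        np.testing.assert_allclose(binned.means, 2.5)

    def test_weighted_mean_conservation(self):
        rng = np.random.default_rng(2)
        pt = rng.random(977)
        X = rng.normal(0, 3, (977, 4))
        binned = cl.bin_pseudotime(pt, X, list("abcd"), n_bins=100)
        overall = (binned.means * binned.counts[:, None]).sum(axis=0) / 977
        np.testing.assert_allclose(overall, X.mean(axis=0), atol=1e-9)

    def test_nonfinite_pseudotime_dropped(self):
        pt = np.array([0.1, np.nan, 0.3, 0.2, np.inf, 0.5])
        X = np.arange(6, dtype=float)[:, None]
        binned = cl.bin_pseudotime(pt, X, ["m"], n_bins=2)
        assert binned.counts.sum() == 4

    @pytest.mark.parametrize("n, bins", [(5, 10), (100, 1)])
    def test_invalid_sizes(self, n, bins):
        with pytest.raises(StatsError):
            cl.bin_pseudotime(np.linspace(0, 1, n), np.zeros((n, 1)), ["m"],
                              n_bins=bins)


class TestDerivative:
    def _linear(self, B=50):
        pt = np.linspace(0, 1, 1000)
        X = pt[:, None].copy()
        return cl.bin_pseudotime(pt, X, ["m"], n_bins=B)

    def test_linear_ramp_constant_rate(self):
        binned = self._linear()
        deriv = cl.expression_derivative(binned, smoothing_window=1)
        np.testing.assert_allclose(deriv.rates[:, 0], 1.0, rtol=1e-6)

    def test_discrete_fundamental_theorem_unsmoothed(self):
        rng = np.random.default_rng(3)
        pt = np.sort(rng.random(800))
        X = rng.normal(0, 1, (800, 3))
        binned = cl.bin_pseudotime(pt, X, list("abc"), n_bins=80)
        deriv = cl.expression_derivative(binned, smoothing_window=1)
        steps = np.diff(binned.midpoints)
        integral = (deriv.rates * steps[:, None]).sum(axis=0)
        np.testing.assert_allclose(integral, binned.means[-1] - binned.means[0],
                                   atol=1e-9)

    def test_constant_marker_no_inflections(self):
        pt = np.linspace(0, 1, 500)
        binned = cl.bin_pseudotime(pt, np.full((500, 1), 1.0), ["m"], n_bins=50)
        deriv = cl.expression_derivative(binned, smoothing_window=5)
        np.testing.assert_allclose(deriv.rates, 0.0, atol=1e-12)
        assert deriv.inflections["m"] == []

    def test_logistic_marker_peak_rate_near_inflection(self):
        # simulator-like marker ramp: amplitude 3, steepness 0.02, noise 0.22
        rng = np.random.default_rng(4)
        t = rng.random(8000)
        t0 = 0.6
        y = (0.3 + 3.0 / (1.0 + np.exp(-(t - t0) / 0.02))
             + rng.normal(0, 0.22, t.size))
        binned = cl.bin_pseudotime(t, y[:, None], ["m"], n_bins=200)
        deriv = cl.expression_derivative(binned, smoothing_window=9)
        peak_bin = deriv.max_rate_bin["m"]
        true_bin = int(np.argmin(np.abs(binned.midpoints - t0)))
        assert abs(peak_bin - true_bin) <= 3

    def test_sign_change_detected(self):
        pt = np.linspace(0, 1, 2000)
        y = np.sin(np.pi * pt)  # rises then falls; derivative flips mid-way
        binned = cl.bin_pseudotime(pt, y[:, None], ["m"], n_bins=100)
        deriv = cl.expression_derivative(binned, smoothing_window=5)
        assert len(deriv.inflections["m"]) == 1
        assert abs(deriv.boundary_mid[deriv.inflections["m"][0]] - 0.5) < 0.05

    @pytest.mark.parametrize("window", [2, 4, 999])
    def test_invalid_window(self, window):
        binned = self._linear(B=50)
        with pytest.raises(StatsError):
            cl.expression_derivative(binned, smoothing_window=window)


class TestDissimilarity:
    def test_identical_rows_zero_distance(self):
        prop = pd.DataFrame([[0.5, 0.5], [0.5, 0.5]], index=["a", "b"])
        dm = cl.sample_dissimilarity(prop)
        assert dm.matrix.loc["a", "b"] == 0.0

    @pytest.mark.parametrize("a, b, expected", [
        ([1.0, 0.0], [0.0, 1.0], 2.0),
        ([0.5, 0.5], [1.0, 0.0], 1.0),
    ])
    def test_manhattan_examples(self, a, b, expected):
        prop = pd.DataFrame([a, b], index=["x", "y"])
        dm = cl.sample_dissimilarity(prop)
        assert dm.matrix.loc["x", "y"] == pytest.approx(expected)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(5)
        raw = rng.random((8, 6))
        prop = pd.DataFrame(raw / raw.sum(axis=1, keepdims=True))
        dm = cl.sample_dissimilarity(prop)
        for i in range(8):
            for j in range(8):
                brute = sum(abs(prop.iloc[i, c] - prop.iloc[j, c])
                            for c in range(6))
                assert dm.matrix.iloc[i, j] == pytest.approx(brute, abs=1e-12)

    def test_triangle_inequality(self):
        rng = np.random.default_rng(6)
        raw = rng.random((6, 4))
        prop = pd.DataFrame(raw / raw.sum(axis=1, keepdims=True))
        D = cl.sample_dissimilarity(prop).matrix.to_numpy()
        for i, j, k in itertools.permutations(range(6), 3):
            assert D[i, j] <= D[i, k] + D[k, j] + 1e-12

    def test_unnormalized_rows_rejected(self):
        prop = pd.DataFrame([[0.5, 0.2], [0.5, 0.5]])
        with pytest.raises(StatsError, match="sum to 1"):
            cl.sample_dissimilarity(prop)

    def test_dendrogram_groups_similar_samples(self):
        prop = pd.DataFrame([[0.9, 0.1], [0.88, 0.12], [0.1, 0.9]],
                            index=["a", "b", "c"])
        dm = cl.sample_dissimilarity(prop)
        order = dm.dendrogram_order()
        assert abs(order.index("a") - order.index("b")) == 1


def brute_force_rank_sum_p(x, y):
    """Exact two-sided rank-sum p by enumerating all label assignments."""
    pooled = np.concatenate([x, y])
    n = len(x)
    ranks = pd.Series(pooled).rank().to_numpy()
    observed = ranks[:n].sum()
    mean = n * (len(pooled) + 1) / 2.0
    stats = [ranks[list(combo)].sum()
             for combo in itertools.combinations(range(len(pooled)), n)]
    stats = np.asarray(stats)
    p = np.mean(np.abs(stats - mean) >= abs(observed - mean) - 1e-12)
    return p


class TestCompareGroups:
    def test_identical_groups_p_one(self):
        values = pd.DataFrame({"f": [1.0, 1.0, 1.0, 1.0]})
        out = cl.compare_groups(values, np.array(["a", "a", "b", "b"]))
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_extreme_separation_exact_p(self):
        values = pd.DataFrame({"f": [1, 2, 3, 10, 11, 12]})
        out = cl.compare_groups(values, np.array(["a"] * 3 + ["b"] * 3))
        assert out.loc[0, "p"] == pytest.approx(0.1, abs=1e-12)

    @pytest.mark.parametrize("nx, ny", [(3, 3), (4, 5), (6, 6), (2, 6)])
    def test_exact_p_matches_enumeration(self, nx, ny):
        rng = np.random.default_rng(nx * 10 + ny)
        for _ in range(5):
            x = rng.permutation(np.arange(1.0, nx + ny + 1))[:nx]
            y = np.setdiff1d(np.arange(1.0, nx + ny + 1), x)
            _, p = _wilcoxon_rank_sum(x, y)
            assert p == pytest.approx(brute_force_rank_sum_p(x, y), abs=1e-12)

    def test_bh_q_monotone_and_at_least_p(self):
        rng = np.random.default_rng(7)
        values = pd.DataFrame(rng.normal(0, 1, (8, 10)),
                              columns=[f"f{i}" for i in range(10)])
        out = cl.compare_groups(values, np.array(["a"] * 4 + ["b"] * 4),
                                fdr_method="bh")
        assert (out["q"] >= out["p"] - 1e-12).all()
        ordered = out.sort_values("p")
        assert (np.diff(ordered["q"]) >= -1e-12).all()

    def test_local_fdr_used_for_large_families(self):
        rng = np.random.default_rng(8)
        values = pd.DataFrame(rng.normal(0, 1, (10, 60)),
                              columns=[f"f{i}" for i in range(60)])
        out = cl.compare_groups(values, np.array(["a"] * 5 + ["b"] * 5))
        assert set(out["fdr_method"]) <= {"local", "bh"}
        assert out["q"].between(0, 1).all()

    def test_small_groups_rejected(self):
        values = pd.DataFrame({"f": [1.0, 2.0, 3.0]})
        with pytest.raises(StatsError, match="at least 2"):
            cl.compare_groups(values, np.array(["a", "b", "b"]))


class TestPercentPositive:
    def test_all_above_threshold(self):
        X = np.full((50, 1), 5.0)
        out = cl.percent_positive(X, ["m"], np.full(50, "s1"),
                                  np.ones(50, bool), {"m": 1.0})
        assert out.loc["s1", "m"] == 100.0

    def test_median_threshold_near_fifty(self):
        rng = np.random.default_rng(9)
        X = rng.normal(0, 1, (501, 1))
        thr = float(np.median(X))
        out = cl.percent_positive(X, ["m"], np.full(501, "s1"),
                                  np.ones(501, bool), {"m": thr})
        assert out.loc["s1", "m"] == pytest.approx(50.0, abs=100.0 / 501 + 1e-9)

    def test_empty_subset_reported_missing(self, caplog):
        X = np.ones((10, 1))
        samples = np.array(["s1"] * 5 + ["s2"] * 5)
        subset = np.array([True] * 5 + [False] * 5)
        with caplog.at_level("WARNING"):
            out = cl.percent_positive(X, ["m"], samples, subset, {"m": 0.0})
        assert np.isnan(out.loc["s2", "m"])
        assert out.loc["s1", "m"] == 100.0
        assert any("empty subset" in r.message for r in caplog.records)

    def test_missing_threshold_rejected(self):
        with pytest.raises(StatsError, match="threshold"):
            cl.percent_positive(np.ones((5, 1)), ["m"], np.full(5, "s"),
                                np.ones(5, bool), {})
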