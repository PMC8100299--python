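"""Functional-ANOVA machinery against independent oracles."""

import numpy as np
import pytest
from scipy import stats
from scipy.interpolate import make_interp_spline

from qar import fanova as fa
from qar.errors import ContractError, DataError, ShapeError


def anova_f_oracle(a, b):
    """Direct sums-of-squares one-way ANOVA F for two samples."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    n1, n2 = a.size, b.size
    grand = np.concatenate([a, b]).mean()
    ssb = n1 * (a.mean() - grand) ** 2 + n2 * (b.mean() - grand) ** 2
    ssw = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    return (ssb / 1.0) / (ssw / (n1 + n2 - 2))


def random_grouped(rng, n1=4, n2=5, n_minutes=10, offset=0.0):
    X = rng.normal(size=(n1 + n2, n_minutes))
    X[:n1] += offset
    labels = ["A"] * n1 + ["B"] * n2
    return fa.build_curves(X, labels)


class TestBuildCurves:
    def test_interpolation_passes_through_knots(self, rng):
        X = rng.normal(size=(4, 8))
        g = fa.build_curves(X, ["A", "A", "B", "B"], dense_size=50)
        for j, c in enumerate(g.curves):
            assert np.allclose(c(c.knots), X[j], atol=1e-12)

    def test_constant_scores_stay_constant_on_dense_grid(self):
        X = np.vstack([np.full(22, 3.3), np.full(22, 3.3), np.zeros(22), np.zeros(22)])
        g = fa.build_curves(X, ["A", "A", "B", "B"])
        assert np.allclose(g.matrix[0], 3.3, atol=1e-12)
        assert g.grid.size == 221

    def test_matches_bspline_oracle_at_random_points(self, rng):
        X = rng.normal(size=(2, 22)).cumsum(axis=1)
        X = np.vstack([X, X])  # 2 per group
        g = fa.build_curves(X, ["A", "B", "A", "B"])
        knots = np.arange(1.0, 23.0)
        pts = rng.uniform(1.0, 22.0, size=10)
        for j in (0, 1):
            oracle = make_interp_spline(knots, X[j], k=3)
            assert np.allclose(g.curves[j](pts), oracle(pts), atol=1e-8)

    def test_ragged_input_rejected(self):
        with pytest.raises(ShapeError):
            fa.build_curves(np.array([[1, 2], [1, 2]], dtype=object)[..., None], ["A", "B"])

    def test_single_group_rejected(self, rng):
        with pytest.raises(DataError):
            fa.build_curves(rng.normal(size=(4, 5)), ["A"] * 4)


class TestPointwiseF:
    def test_coincident_group_means_give_zero(self):
        X = np.array([[1.0], [3.0], [0.0], [4.0]])  # both means = 2
        g = fa.build_curves(np.tile(X, (1, 4)), ["A", "A", "B", "B"])
        assert np.allclose(fa.pointwise_F(g), 0.0, atol=1e-12)

    def test_hand_anova_example(self):
        X = np.tile(np.array([[0.0], [2.0], [3.0], [5.0]]), (1, 4))
        g = fa.build_curves(X, ["A", "A", "B", "B"])
        # SSB = 9, SSW = 4, F = (9/1)/(4/2) = 4.5
        assert np.allclose(fa.pointwise_F(g), 4.5, atol=1e-12)

    def test_matches_oracle_on_random_configurations(self, rng):
        for _ in range(50):
            n1 = int(rng.integers(2, 8))
            n2 = int(rng.integers(2, 8))
            vals = rng.normal(size=n1 + n2)
            X = np.tile(vals[:, None], (1, 4))
            g = fa.build_curves(X, ["A"] * n1 + ["B"] * n2)
            expected = anova_f_oracle(vals[:n1], vals[n1:])
            scipy_f, _ = stats.f_oneway(vals[:n1], vals[n1:])
            got = fa.pointwise_F(g)[0]
            assert got == pytest.approx(expected, abs=1e-10)
            assert got == pytest.approx(scipy_f, abs=1e-8)

    def test_degenerate_within_variance_flagged_infinite(self):
        X = np.tile(np.array([[1.0], [1.0], [2.0], [2.0]]), (1, 4))
        g = fa.build_curves(X, ["A", "A", "B", "B"])
        assert np.all(np.isinf(fa.pointwise_F(g)))


class TestResamplingTests:
    def test_identical_groups_statistic_zero_p_one(self, rng):
        half = rng.normal(size=(3, 8))
        X = np.vstack([half, half])
        g = fa.build_curves(X, ["A"] * 3 + ["B"] * 3)
        gpf = fa.gpf_test(g, n_resamples=199, seed=0)
        fmax = fa.fmax_test(g, n_resamples=199, seed=0)
        assert gpf.statistic == pytest.approx(0.0, abs=1e-12) and gpf.p_value == 1.0
        assert fmax.statistic == pytest.approx(0.0, abs=1e-12) and fmax.p_value == 1.0

    def test_gpf_statistic_matches_trapezoid_oracle(self, rng):
        g = random_grouped(rng)
        F = np.array(
            [anova_f_oracle(col[:4], col[4:]) for col in g.matrix.T]
        )
        expected = np.trapezoid(F, g.grid) / (g.grid[-1] - g.grid[0])
        res = fa.gpf_test(g, n_resamples=99, seed=1)
        assert res.statistic == pytest.approx(expected, abs=1e-10)

    def test_fmax_statistic_is_grid_maximum(self, rng):
        g = random_grouped(rng)
        expected = max(anova_f_oracle(col[:4], col[4:]) for col in g.matrix.T)
        res = fa.fmax_test(g, n_resamples=99, seed=1)
        assert res.statistic == np.max(fa.pointwise_F(g))
        assert res.statistic == pytest.approx(expected, abs=1e-10)

    def test_p_values_bounded_below_and_reproducible(self, rng):
        g = random_grouped(rng, offset=2.0)
        a = fa.gpf_test(g, n_resamples=199, seed=5)
        b = fa.gpf_test(g, n_resamples=199, seed=5)
        assert a.p_value == b.p_value
        assert a.p_value >= 1.0 / 200.0

    def test_label_swap_symmetry(self, rng):
        X = rng.normal(size=(9, 10))
        labels = ["A"] * 4 + ["B"] * 5
        swapped = ["B" if l == "A" else "A" for l in labels]
        r1 = fa.mean_function_tests(fa.build_curves(X, labels), 199, seed=3)
        r2 = fa.mean_function_tests(fa.build_curves(X, swapped), 199, seed=3)
        for a, b in zip(r1, r2):
            assert a.statistic == pytest.approx(b.statistic, abs=1e-12)
            assert a.p_value == b.p_value

    def test_shared_engine_consistent_with_individual_calls(self, rng):
        g = random_grouped(rng, offset=1.0)
        gpf, fmax = fa.mean_function_tests(g, 199, seed=9)
        assert gpf.statistic == fa.gpf_test(g, 199, seed=9).statistic
        assert fmax.p_value == fa.fmax_test(g, 199, seed=9).p_value


class TestVelocity:
    def test_constant_curve_zero_velocity(self):
        X = np.vstack([np.full(10, 2.0)] * 4)
        g = fa.build_curves(X, ["A", "A", "B", "B"])
        v = fa.velocity(g)
        assert np.allclose(v.matrix, 0.0, atol=1e-12)
        assert v.units == "score/minute"

    def test_linear_curve_constant_slope(self):
        t = np.arange(1.0, 11.0)
        X = np.vstack([3.0 * t, 3.0 * t, -t, -t])
        g = fa.build_curves(X, ["A", "A", "B", "B"])
        v = fa.velocity(g)
        assert np.allclose(v.matrix[0], 3.0, atol=1e-9)
        assert np.allclose(v.matrix[2], -1.0, atol=1e-9)

    def test_matches_central_differences_at_interior_knots(self, rng):
        t = np.arange(1.0, 23.0)
        X = np.sin(0.3 * t)[None, :] + 0.01 * rng.normal(size=(4, 22))
        g = fa.build_curves(X, ["A", "A", "B", "B"])
        v = fa.velocity(g)
        for j, c in enumerate(g.curves):
            fd = (c.values[2:] - c.values[:-2]) / 2.0
            spline_d = v.curves[j](t[1:-1])
            assert np.allclose(spline_d, fd, rtol=0.05, atol=0.02)


class TestPointwiseDistribution:
    def test_constant_group_means(self):
        X = np.vstack([np.full(22, 5.0)] * 2 + [np.full(22, 1.0)] * 3)
        g = fa.build_curves(X, ["A", "A", "B", "B", "B"])
        d = fa.pointwise_distribution(g)
        assert np.allclose(d["A"]["mean"], 5.0)
        assert np.allclose(d["B"]["mean"], 1.0)
        assert d["A"]["values"].shape == (2, 5)

    def test_means_match_direct_loop_oracle(self, rng):
        g = random_grouped(rng, n_minutes=22)
        times = [3.0, 7.0, 9.0, 11.0, 22.0]
        d = fa.pointwise_distribution(g, times)
        for gi, name in enumerate(g.groups):
            for ti, t in enumerate(times):
                vals = [c(t) for c in g.curves if c.group == name]
                assert d[name]["mean"][ti] == pytest.approx(np.mean(vals), abs=1e-12)

    def test_time_outside_domain_rejected(self, rng):
        g = random_grouped(rng, n_minutes=10)
        with pytest.raises(DataError):
            fa.pointwise_distribution(g, [11.0])


class TestScalarStats:
    def test_spearman_perfect_and_reversed(self):
        x = np.array([1.0, 2.0, 3.0, 5.0, 9.0])
        assert fa.spearman_corr(x, x)[0] == pytest.approx(1.0)
        assert fa.spearman_corr(x, -x)[0] == pytest.approx(-1.0)

    def test_spearman_with_ties_matches_midrank_oracle(self, rng):
        for _ in range(20):
            x = rng.integers(0, 4, size=6).astype(float)
            y = rng.integers(0, 4, size=6).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            rx = stats.rankdata(x)
            ry = stats.rankdata(y)
            oracle = np.corrcoef(rx, ry)[0, 1]
            assert fa.spearman_corr(x, y)[0] == pytest.approx(oracle, abs=1e-12)

    def test_spearman_constant_input_signalled(self):
        with pytest.raises(DataError):
            fa.spearman_corr(np.ones(5), np.arange(5.0))

    def test_curve_total_constant_rectangle(self):
        X = np.vstack([np.full(22, 2.0)] * 4)
        g = fa.build_curves(X, ["A", "A", "B", "B"])
        assert fa.curve_total(g.curves[0]) == pytest.approx(21.0 * 2.0, rel=1e-12)

    def test_curve_total_matches_fine_riemann_oracle(self):
        t = np.arange(1.0, 23.0)
        smooth = 2.0 + np.sin(0.3 * t)
        g = fa.build_curves(np.vstack([smooth] * 4), ["A", "A", "B", "B"])
        c = g.curves[0]
        tt = np.linspace(1.0, 22.0, 200001)
        riemann = np.sum(c(tt)[:-1] * np.diff(tt))
        assert fa.curve_total(c) == pytest.approx(riemann, rel=1e-3)

    def test_exact_ranksum_small_sample(self):
        p = fa.scalar_group_compare(
            np.array([1.0, 2.0, 3.0, 4.0]), np.array(["x", "x", "y", "y"])
        )
        assert p == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_ranksum_invariant_to_monotone_transform(self, rng):
        vals = rng.normal(size=10)
        labels = np.array(["x"] * 5 + ["y"] * 5)
        p1 = fa.scalar_group_compare(vals, labels)
        p2 = fa.scalar_group_compare(np.exp(vals), labels)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_large_sample_matches_scipy_oracle(self, rng):
        x = rng.normal(size=12)
        y = rng.normal(size=10) + 0.5
        vals = np.concatenate([x, y])
        labels = np.array(["x"] * 12 + ["y"] * 10)
        p = fa.scalar_group_compare(vals, labels)
        _, expected = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert p == pytest.approx(expected, abs=1e-12)

    def test_ranksum_null_p_distribution_uniform(self, rng):
        # identical pooled samples split at random: P(p <= c) should be ~c
        pooled = rng.normal(size=10)
        ps = []
        for _ in range(2000):
            perm = rng.permutation(10)
            vals = pooled[perm]
            ps.append(fa.scalar_group_compare(vals, np.array(["x"] * 5 + ["y"] * 5)))
        ps = np.asarray(ps)
        for c in (0.1, 0.3, 0.5):
            # discrete support: empirical CDF must not exceed c by much
            assert np.mean(ps <= c) <= c + 0.05

    def test_chi_square_matches_scipy(self):
        vals = np.array(["m"] * 6 + ["f"] * 4 + ["m"] * 10 + ["f"] * 5)
        labels = np.array(["ADHD"] * 10 + ["HC"] * 15)
        p = fa.scalar_group_compare(vals, labels, kind="categorical")
        table = np.array([[6, 4], [10, 5]])
        _, expected, _, _ = stats.chi2_contingency(table, correction=False)
        assert p == pytest.approx(expected, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ContractError):
            fa.scalar_group_compare(np.arange(3.0), np.array(["x", "x", "x"]))
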