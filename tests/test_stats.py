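import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dynconn import (
    EdgeSeries,
    EdgeSummary,
    SinusoidSpec,
    edge_pairs,
    generate_sinusoid,
    group_average,
    mean_variance_scaling,
    summarize_edges,
)
from oracles import sample_variance, spearman as brute_spearman


def _edge_series(values, w=5):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    e = values.shape[0]
    # smallest node count whose upper triangle holds e edges
    n = 2
    while n * (n - 1) // 2 < e:
        n += 1
    return EdgeSeries(values=values, window_length=w, method="pearson",
                      edge_index=edge_pairs(n)[:e])


def _summary(mean, variance, n_windows=50):
    mean = np.asarray(mean, dtype=float)
    e = mean.size
    n = 2
    while n * (n - 1) // 2 < e:
        n += 1
    return EdgeSummary(edge_index=edge_pairs(n)[:e], mean=mean,
                       variance=np.asarray(variance, dtype=float),
                       n_windows=np.full(e, n_windows))


class TestSummarize:
    def test_hand_computable_cases(self):
        s = summarize_edges(_edge_series([[0.7, 0.7, 0.7],
                                          [0.1, 0.3, 0.5]]))
        np.testing.assert_allclose(s.mean, [0.7, 0.3])
        np.testing.assert_allclose(s.variance, [0.0, 0.04], atol=1e-15)
        np.testing.assert_array_equal(s.n_windows, [3, 3])

    def test_sinusoid_over_full_periods_matches_direct_summation(self):
        v = generate_sinusoid(SinusoidSpec(0.0, 0.2, 60, np.pi, 240))
        s = summarize_edges(_edge_series(v))
        assert s.mean[0] == pytest.approx(0.0, abs=1e-14)
        brute = sample_variance(list(v))
        assert s.variance[0] == pytest.approx(brute, rel=1e-12)
        # population variance of a full-period sinusoid is A^2/2 = 0.02
        assert s.variance[0] == pytest.approx(0.02, rel=0.01)

    def test_nan_windows_excluded_with_counts(self):
        vals = np.array([[0.1, np.nan, 0.3, 0.5],
                         [0.2, 0.2, 0.2, 0.2]])
        s = summarize_edges(_edge_series(vals))
        assert s.n_windows.tolist() == [3, 4]
        assert s.mean[0] == pytest.approx(0.3)
        assert s.variance[0] == pytest.approx(0.04)

    def test_edge_with_fewer_than_two_windows_is_named(self):
        vals = np.array([[0.1, 0.2, 0.3],
                         [0.4, np.nan, np.nan]])
        with pytest.raises(ValueError, match=r"edge \(0, 2\)"):
            summarize_edges(_edge_series(vals))

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_bounded_variance_inequality_holds(self, seed):
        # correlations live in [-1, 1]; the sample variance can never
        # exceed the (n/(n-1))-corrected bounded-variable bound
        rng = np.random.default_rng(seed)
        vals = np.clip(rng.normal(0.2, 0.5, size=(10, 12)), -1, 1)
        s = summarize_edges(_edge_series(vals, w=4))
        n = s.n_windows
        bound = (1 - s.mean) * (1 + s.mean) * n / (n - 1)
        assert np.all(s.variance <= bound + 1e-12)


class TestGroupAverage:
    def test_single_subject_is_identity(self):
        s = _summary([0.1, 0.5], [0.01, 0.02])
        g = group_average([s])
        np.testing.assert_array_equal(g.mean, s.mean)
        np.testing.assert_array_equal(g.variance, s.variance)

    def test_elementwise_mean_and_subject_order_invariance(self):
        a = _summary([0.0, 0.4], [0.01, 0.03])
        b = _summary([0.2, 0.0], [0.03, 0.09])
        g1 = group_average([a, b])
        g2 = group_average([b, a])
        np.testing.assert_allclose(g1.variance, [0.02, 0.06])
        np.testing.assert_allclose(g1.mean, [0.1, 0.2])
        np.testing.assert_array_equal(g1.mean, g2.mean)
        np.testing.assert_array_equal(g1.variance, g2.variance)

    def test_mismatched_edge_sets_rejected(self):
        a = _summary([0.1, 0.2], [0.0, 0.0])
        b = _summary([0.1, 0.2, 0.3], [0.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="mismatch"):
            group_average([a, b])

    def test_group_means_near_truth_on_simulated_cohort(
            self, designed_cohort, designed_summaries):
        from dynconn import window_average
        g = group_average(designed_summaries)
        labels = np.array(designed_cohort.partition.labels)
        ei = g.edge_index
        within = labels[ei[:, 0]] == labels[ei[:, 1]]
        gt = designed_cohort.ground_truth
        # time-averaged model correlations (windowing preserves the mean
        # up to edge effects); Spearman compresses them slightly, so a
        # modest absolute tolerance
        truth_within = float(np.mean(window_average(
            gt.within_corr[labels[0]], 45)))
        truth_between = float(np.mean(window_average(gt.between_corr, 45)))
        assert np.mean(g.mean[within]) == pytest.approx(truth_within,
                                                        abs=0.05)
        assert np.mean(g.mean[~within]) == pytest.approx(truth_between,
                                                         abs=0.05)


class TestScaling:
    def test_monotone_relationships_give_unit_rho(self):
        mu = np.linspace(0.1, 0.8, 20)
        up = mean_variance_scaling(_summary(mu, 0.1 * mu + 0.01))
        down = mean_variance_scaling(_summary(mu, 0.1 * (1 - mu) + 0.01))
        assert up.rho == pytest.approx(1.0)
        assert down.rho == pytest.approx(-1.0)
        assert up.p_value < 1e-6

    def test_matches_brute_force_rank_oracle(self, rng):
        mu = rng.uniform(-0.5, 0.9, 20)
        var = rng.uniform(0.0, 0.05, 20)
        res = mean_variance_scaling(_summary(mu, var))
        assert res.rho == pytest.approx(
            brute_spearman(list(mu), list(var)), abs=1e-12)
        assert res.n_edges == 20

    def test_zero_spread_is_an_error(self):
        with pytest.raises(ValueError, match="zero spread"):
            mean_variance_scaling(_summary([0.5, 0.5, 0.5],
                                           [0.01, 0.02, 0.03]))

    def test_exact_permutation_p_for_tiny_edge_sets(self):
        mu = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        var = np.array([0.05, 0.04, 0.03, 0.02, 0.01])
        res = mean_variance_scaling(_summary(mu, var), exact=True)
        assert res.rho == pytest.approx(-1.0)
        # 2 of 5! = 120 orderings reach |rho| = 1
        assert res.p_value == pytest.approx(2 / 120)
        assert res.method == "exact-permutation"
        with pytest.raises(ValueError, match="<= 9"):
            mean_variance_scaling(
                _summary(np.arange(10) / 10.0, np.arange(10) / 100.0),
                exact=True)

    def test_needs_at_least_three_edges(self):
        with pytest.raises(ValueError, match="at least 3"):
            mean_variance_scaling(_summary([0.1, 0.2], [0.01, 0.02]))
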