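from itertools import combinations

import numpy as np
import pytest

from dynconn import (
    EdgeSummary,
    NodePartition,
    classify_edges,
    edge_pairs,
    n_edges,
    plot_variance_matrix,
    variance_contrast,
    variance_matrix,
)


def _summary(variance, n_nodes, mean=None):
    variance = np.asarray(variance, dtype=float)
    ei = edge_pairs(n_nodes)
    assert ei.shape[0] == variance.size
    if mean is None:
        mean = np.zeros_like(variance)
    return EdgeSummary(edge_index=ei, mean=mean, variance=variance,
                       n_windows=np.full(variance.size, 50))


class TestClassify:
    def test_single_label_makes_every_edge_within(self):
        mask = classify_edges(edge_pairs(5), NodePartition(["X"] * 5))
        assert mask.all()

    def test_three_node_case(self):
        mask = classify_edges(edge_pairs(3), NodePartition(["A", "A", "B"]))
        # edges in order (0,1), (0,2), (1,2)
        assert mask.tolist() == [True, False, False]

    def test_equal_blocks_match_exhaustive_enumeration(self):
        labels = [f"B{k}" for k in range(4) for _ in range(10)]
        mask = classify_edges(edge_pairs(40), NodePartition(labels))
        brute = sum(1 for i, j in combinations(range(40), 2)
                    if labels[i] == labels[j])
        assert brute == 4 * 10 * 9 // 2 == 180
        assert int(mask.sum()) == brute
        # the two classes partition the edge set
        assert mask.size == n_edges(40)
        assert int(mask.sum()) + int((~mask).sum()) == n_edges(40)

    def test_unlabeled_node_is_reported(self):
        with pytest.raises(ValueError, match="node 3"):
            classify_edges(edge_pairs(4), NodePartition(["A", "A", "B"]))


class TestContrast:
    def test_identical_classes_give_null_result(self):
        part = NodePartition(["A", "A", "B", "B"])
        summaries = [_summary([0.02] * 6, 4) for _ in range(4)]
        res = variance_contrast(summaries, part)
        assert res.t_statistic == 0.0
        assert res.p_value == 1.0
        assert not res.degenerate

    def test_constant_nonzero_difference_is_flagged_degenerate(self):
        part = NodePartition(["A", "A", "B", "B"])
        # within edge (0,1),(2,3) variance 0.01; between 0.03, all subjects
        v = np.array([0.01, 0.03, 0.03, 0.03, 0.03, 0.01])
        summaries = [_summary(v, 4) for _ in range(3)]
        res = variance_contrast(summaries, part)
        assert res.degenerate
        assert np.isnan(res.t_statistic) and np.isnan(res.p_value)

    def test_designed_cohort_shows_higher_between_variance(
            self, designed_summaries, designed_cohort):
        res = variance_contrast(designed_summaries,
                                designed_cohort.partition)
        assert np.all(res.between_mean_variance
                      > res.within_mean_variance)
        assert res.t_statistic < 0
        assert res.p_value < 0.05
        assert res.n_subjects == 20

    def test_subject_and_edge_order_invariance(self, rng):
        part = NodePartition(["A", "A", "B", "B"])
        summaries = [_summary(rng.uniform(0.0, 0.1, 6), 4)
                     for _ in range(5)]
        res = variance_contrast(summaries, part)
        resr = variance_contrast(summaries[::-1], part)
        assert res.t_statistic == pytest.approx(resr.t_statistic)
        # shuffling edges (with their index rows) changes nothing
        perm = rng.permutation(6)
        shuffled = [EdgeSummary(edge_index=s.edge_index[perm],
                                mean=s.mean[perm],
                                variance=s.variance[perm],
                                n_windows=s.n_windows[perm])
                    for s in summaries]
        ress = variance_contrast(shuffled, part)
        assert ress.t_statistic == pytest.approx(res.t_statistic)

    def test_swapping_class_variances_negates_t(self, rng):
        # give each subject a constant variance per class, then exchange
        # the two class values: the paired t statistic flips sign exactly
        part = NodePartition(["A", "A", "B", "B"])
        within_mask = classify_edges(edge_pairs(4), part)
        base, swapped = [], []
        for _ in range(6):
            w_val, b_val = rng.uniform(0.0, 0.1, 2)
            base.append(_summary(np.where(within_mask, w_val, b_val), 4))
            swapped.append(_summary(np.where(within_mask, b_val, w_val), 4))
        t_base = variance_contrast(base, part).t_statistic
        t_swap = variance_contrast(swapped, part).t_statistic
        assert t_swap == pytest.approx(-t_base, rel=1e-12)

    def test_validation_errors(self, rng):
        part = NodePartition(["A", "A", "B", "B"])
        one = [_summary(rng.uniform(0, 0.1, 6), 4)]
        with pytest.raises(ValueError, match="2 subjects"):
            variance_contrast(one, part)
        single_class = NodePartition(["A", "A", "A", "A"])
        with pytest.raises(ValueError, match="nonempty"):
            variance_contrast(one * 2, single_class)

    def test_unpaired_option_runs(self, rng):
        part = NodePartition(["A", "A", "B", "B"])
        summaries = [_summary(rng.uniform(0, 0.1, 6), 4)
                     for _ in range(5)]
        res = variance_contrast(summaries, part, paired=False)
        assert not res.paired
        assert np.isfinite(res.t_statistic)


class TestVarianceMatrix:
    def test_three_node_mirror_with_missing_diagonal(self):
        s = _summary([0.01, 0.02, 0.03], 3)  # (0,1), (0,2), (1,2)
        mat, order = variance_matrix(s, NodePartition(["A", "A", "B"]))
        assert order.tolist() == [0, 1, 2]
        assert np.isnan(np.diag(mat)).all()
        assert mat[0, 1] == mat[1, 0] == 0.01
        assert mat[0, 2] == mat[2, 0] == 0.02
        assert mat[1, 2] == mat[2, 1] == 0.03

    def test_grouping_permutes_rows_consistently(self):
        s = _summary([0.01, 0.02, 0.03], 3)
        # interleaved labels: node 1 moves to the back
        mat, order = variance_matrix(s, NodePartition(["A", "B", "A"]))
        assert order.tolist() == [0, 2, 1]
        assert mat[0, 1] == 0.02  # now the (0,2) edge
        assert mat[0, 2] == 0.01
        assert mat[1, 2] == 0.03

    def test_block_structure_visible_in_matrix(self, designed_cohort,
                                               designed_summaries):
        from dynconn import group_average
        g = group_average(designed_summaries)
        part = designed_cohort.partition
        mat, order = variance_matrix(g, part)
        n = part.n_nodes
        labels = np.array([part.labels[k] for k in order])
        same = labels[:, None] == labels[None, :]
        off_diag = ~np.eye(n, dtype=bool)
        within_avg = np.nanmean(mat[same & off_diag])
        between_avg = np.nanmean(mat[~same])
        assert within_avg < between_avg

    def test_heatmap_written(self, tmp_path, rng):
        s = _summary(rng.uniform(0, 0.1, 15), 6)
        part = NodePartition(["A", "A", "B", "B", "C", "C"])
        out = tmp_path / "variance.png"
        plot_variance_matrix(s, part, str(out))
        assert out.stat().st_size > 0
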