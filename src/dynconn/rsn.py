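"""Within- vs between-network edge contrast.

A node partition (e.g. resting-state network labels) splits the edges into
a within class (both endpoints share a label) and a between class.  The
contrast compares the two classes' average temporal variances per subject
and tests the per-subject difference with a paired two-tailed t-test.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .datatypes import ContrastResult, EdgeSummary, NodePartition

__all__ = ["classify_edges", "variance_contrast", "variance_matrix",
           "plot_variance_matrix"]


def classify_edges(edge_index: np.ndarray,
                   partition: NodePartition) -> np.ndarray:
    """Boolean mask over edges: True where both endpoints share a label.

    Every node referenced by ``edge_index`` must be labelled.
    """
    edge_index = np.asarray(edge_index, dtype=np.int64)
    labels = np.asarray(partition.labels, dtype=object)
    max_node = int(edge_index.max())
    if max_node >= len(labels):
        raise ValueError(f"node {max_node} has no label in the partition")
    return labels[edge_index[:, 0]] == labels[edge_index[:, 1]]


def variance_contrast(
    summaries: list[EdgeSummary],
    partition: NodePartition,
    paired: bool = True,
) -> ContrastResult:
    """Compare within- vs between-class mean edge variance across subjects.

    Per subject, every edge weighs equally inside its class (no
    per-network normalization).  With ``paired=True`` (default) the test
    is a two-tailed paired t-test on the per-subject (within, between)
    pairs; ``paired=False`` uses an independent two-sample t-test.

    If the two classes are identical for every subject (all per-subject
    differences zero) there is no effect and t = 0, p = 1.  A paired
    design in which every subject shows the same *nonzero* difference has
    zero variance in the differences; the t statistic is then undefined
    and the result is flagged ``degenerate`` with NaN t/p rather than
    reporting an infinite statistic.
    """
    if len(summaries) < 2:
        raise ValueError("need at least 2 subjects")
    w_means = []
    b_means = []
    for s in summaries:
        within = classify_edges(s.edge_index, partition)
        if not within.any() or within.all():
            raise ValueError("both edge classes must be nonempty")
        w_means.append(float(np.mean(s.variance[within])))
        b_means.append(float(np.mean(s.variance[~within])))
    w = np.array(w_means)
    b = np.array(b_means)
    degenerate = False
    if paired:
        diff = w - b
        if np.ptp(diff) == 0:
            if diff[0] == 0:
                t, p = 0.0, 1.0
            else:
                degenerate = True
                t, p = float("nan"), float("nan")
        else:
            t, p = stats.ttest_rel(w, b)
    else:
        if np.ptp(w) == 0 and np.ptp(b) == 0:
            if w[0] == b[0]:
                t, p = 0.0, 1.0
            else:
                degenerate = True
                t, p = float("nan"), float("nan")
        else:
            t, p = stats.ttest_ind(w, b)
    return ContrastResult(
        within_mean_variance=w,
        between_mean_variance=b,
        t_statistic=float(t),
        p_value=float(p),
        n_subjects=len(summaries),
        paired=paired,
        degenerate=degenerate,
    )


def variance_matrix(
    summary: EdgeSummary, partition: NodePartition
) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric node x node matrix of edge variances, grouped by network.

    Rows/columns are permuted so nodes of the same network are contiguous,
    networks ordered by first appearance in the partition.  The diagonal
    (self-pairing, no edge) is NaN.

    Returns
    -------
    matrix : ndarray, shape (N, N)
    order : ndarray of original node indices giving the display order
    """
    labels = list(partition.labels)
    n = len(labels)
    e_max = int(summary.edge_index.max())
    if e_max >= n:
        raise ValueError(f"node {e_max} has no label in the partition")
    full = np.full((n, n), np.nan)
    i, j = summary.edge_index.T
    full[i, j] = summary.variance
    full[j, i] = summary.variance
    order = np.concatenate([
        [k for k, lab in enumerate(labels) if lab == net]
        for net in partition.networks
    ]).astype(np.int64)
    return full[np.ix_(order, order)], order


def plot_variance_matrix(summary: EdgeSummary, partition: NodePartition,
                         out_path: str) -> None:
    """Heatmap of the network-ordered variance matrix (PNG/SVG by suffix)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mat, order = variance_matrix(summary, partition)
    ordered_labels = [partition.labels[k] for k in order]
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(mat, cmap="viridis", interpolation="nearest")
    fig.colorbar(im, ax=ax, label="temporal variance of edge correlation")
    # tick at the centre of each network block
    ticks, names = [], []
    start = 0
    for net in partition.networks:
        size = ordered_labels.count(net)
        ticks.append(start + size / 2 - 0.5)
        names.append(net)
        start += size
    ax.set_xticks(ticks, names, rotation=90, fontsize=7)
    ax.set_yticks(ticks, names, fontsize=7)
    ax.set_title("Edge variance by network")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
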