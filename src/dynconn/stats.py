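"""Per-edge summary statistics and the mean-variance scaling test.

Each edge's windowed-correlation trajectory is reduced to its temporal mean
and unbiased variance; summaries are averaged element-wise across subjects;
the group-level mean and variance vectors are then rank-correlated once
across edges.  A positive rank correlation is the classical mean-variance
scaling of count data (Taylor's law); connectivity time-series instead show
a negative relation, because an edge whose correlation sits near the +1
ceiling has little room left to fluctuate.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
from scipy import stats

from .datatypes import EdgeSeries, EdgeSummary, ScalingResult

__all__ = ["summarize_edges", "group_average", "mean_variance_scaling"]


def summarize_edges(es: EdgeSeries) -> EdgeSummary:
    """Temporal mean and unbiased (n-1) variance per edge.

    NaN windows (undefined correlations) are excluded per edge; an edge
    left with fewer than 2 usable windows is an error, named by its node
    pair.
    """
    vals = es.values
    ok = np.isfinite(vals)
    counts = ok.sum(axis=1)
    bad = np.nonzero(counts < 2)[0]
    if bad.size:
        i, j = es.edge_index[bad[0]]
        raise ValueError(
            f"edge ({i}, {j}) has {counts[bad[0]]} usable windows (< 2); "
            f"{bad.size} edge(s) affected"
        )
    mean = np.nanmean(vals, axis=1)
    variance = np.nanvar(vals, axis=1, ddof=1)
    return EdgeSummary(
        edge_index=es.edge_index,
        mean=mean,
        variance=variance,
        n_windows=counts,
    )


def group_average(summaries: list[EdgeSummary]) -> EdgeSummary:
    """Element-wise average of per-edge means and variances across subjects.

    All summaries must share the same edge index.  ``n_windows`` in the
    result is the per-edge minimum across subjects (the most conservative
    count for downstream variance bounds).
    """
    if not summaries:
        raise ValueError("no summaries to average")
    ref = summaries[0]
    for s in summaries[1:]:
        if not np.array_equal(s.edge_index, ref.edge_index):
            raise ValueError("summaries have mismatched edge sets")
    mean = np.mean([s.mean for s in summaries], axis=0)
    variance = np.mean([s.variance for s in summaries], axis=0)
    n_windows = np.min([s.n_windows for s in summaries], axis=0)
    return EdgeSummary(
        edge_index=ref.edge_index,
        mean=mean,
        variance=variance,
        n_windows=n_windows,
    )


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho: float) -> float:
    """Two-sided exact permutation p for small n (all n! orderings)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(rx)
    obs = abs(rho)
    hits = 0
    total = 0
    for perm in permutations(range(n)):
        r = np.corrcoef(rx, ry[list(perm)])[0, 1]
        if abs(r) >= obs - 1e-12:
            hits += 1
        total += 1
    return hits / total


def mean_variance_scaling(
    summary: EdgeSummary, exact: bool = False
) -> ScalingResult:
    """Spearman rank correlation between per-edge means and variances.

    Parameters
    ----------
    summary : EdgeSummary
        Typically the group-averaged summary; the correlation is computed
        once across edges (not per subject).
    exact : bool
        Use an exact permutation p-value instead of the two-sided
        t-approximation with ``n_edges - 2`` degrees of freedom.  Only
        allowed for ``n_edges <= 9`` (n! orderings are enumerated).

    Returns
    -------
    ScalingResult
        rho in [-1, 1]; a negative rho means high-mean edges fluctuate
        less, the opposite of Taylor's-law scaling.
    """
    n = summary.n_edges
    if n < 3:
        raise ValueError(f"need at least 3 edges, got {n}")
    if np.ptp(summary.mean) == 0 or np.ptp(summary.variance) == 0:
        raise ValueError(
            "rank correlation undefined: zero spread in means or variances"
        )
    rho, p = stats.spearmanr(summary.mean, summary.variance)
    method = "t-approximation"
    if exact:
        if n > 9:
            raise ValueError("exact permutation p only for n_edges <= 9")
        p = _spearman_exact_p(summary.mean, summary.variance, rho)
        method = "exact-permutation"
    return ScalingResult(
        rho=float(rho), p_value=float(p), n_edges=n, method=method
    )
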