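"""Sliding-window edge correlation.

A fixed-length window is advanced one sample at a time over the node signal
matrix; at each position the correlation between every node pair is computed,
giving one trajectory per edge.  With ``T`` samples and window length ``w``
there are exactly ``W = T - w + 1`` full windows (a window starting later
than ``T - w`` would run off the end of the series).

The rank-based (Spearman) coefficient is the default: with short windows it
is less sensitive to outlying samples than the product-moment (Pearson)
coefficient, which is available as an alternative.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import EdgeSeries, RoiTimeSeries, edge_pairs

__all__ = [
    "SlidingWindowConnectivity",
    "sliding_window_correlation",
    "seconds_to_samples",
]

logger = logging.getLogger(__name__)

_METHODS = ("spearman", "pearson")


def seconds_to_samples(duration: float, tr: float) -> int:
    """Convert a duration in seconds to a whole number of samples.

    Parameters
    ----------
    duration : float
        Window duration in seconds; must be a positive integer multiple
        of ``tr``.
    tr : float
        Sampling interval in seconds.

    Returns
    -------
    int
        ``duration / tr`` as an exact integer.

    Raises
    ------
    ValueError
        If the ratio is not an integer (no silent rounding) or either
        argument is non-positive.
    """
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    if tr <= 0:
        raise ValueError(f"tr must be positive, got {tr}")
    ratio = duration / tr
    n = round(ratio)
    if abs(ratio - n) > 1e-9 * max(1.0, abs(ratio)):
        raise ValueError(
            f"duration {duration} s is not an integer multiple of tr {tr} s "
            f"(ratio {ratio})"
        )
    return int(n)


class SlidingWindowConnectivity(BaseEstimator, TransformerMixin):
    """Transform a nodes x time matrix into an edges x windows matrix.

    Parameters
    ----------
    window_length : int
        Window length in samples, ``2 <= window_length <= n_timepoints``.
    method : {"spearman", "pearson"}
        Correlation coefficient computed within each window.  Spearman
        ranks each node's window segment (average ranks on ties) and takes
        the product-moment correlation of the ranks.

    Attributes
    ----------
    n_nodes_ : int
        Number of node rows seen in fit.
    edge_index_ : ndarray, shape (E, 2)
        Upper-triangle row-major (i < j) node-pair index.
    n_windows_ : int
        ``T - window_length + 1`` after transform.
    nan_count_ : int
        Number of undefined correlations (constant window segments) in the
        last transform; such cells are emitted as NaN.
    """

    def __init__(self, window_length: int = 45, method: str = "spearman"):
        self.window_length = window_length
        self.method = method

    def _validate(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (nodes x time)")
        n, t = X.shape
        if n < 2:
            raise ValueError(f"need at least 2 nodes, got {n}")
        if self.method not in _METHODS:
            raise ValueError(
                f"method must be one of {_METHODS}, got {self.method!r}"
            )
        w = self.window_length
        if not isinstance(w, (int, np.integer)) or isinstance(w, bool):
            raise TypeError("window_length must be an integer")
        if w < 2:
            raise ValueError(f"window_length must be >= 2, got {w}")
        if w > t:
            raise ValueError(
                f"window_length {w} exceeds series length {t}"
            )
        return X

    def fit(self, X, y=None):
        X = self._validate(X)
        self.n_nodes_ = X.shape[0]
        self.edge_index_ = edge_pairs(self.n_nodes_)
        return self

    def transform(self, X) -> np.ndarray:
        X = self._validate(X)
        n, t = X.shape
        if not hasattr(self, "edge_index_") or self.n_nodes_ != n:
            self.fit(X)
        w = self.window_length
        n_win = t - w + 1
        iu = np.triu_indices(n, k=1)
        out = np.empty((iu[0].size, n_win))
        nan_count = 0
        for start in range(n_win):
            seg = X[:, start:start + w]
            if self.method == "spearman":
                seg = rankdata(seg, axis=1)
            sd = seg.std(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                corr = np.corrcoef(seg)
            if np.any(sd == 0):
                # constant segment: correlation undefined for its edges
                corr[sd == 0, :] = np.nan
                corr[:, sd == 0] = np.nan
            vals = corr[iu]
            nan_count += int(np.isnan(vals).sum())
            # clip float fuzz so downstream range checks are exact
            out[:, start] = np.clip(vals, -1.0, 1.0)
        self.n_windows_ = n_win
        self.nan_count_ = nan_count
        if nan_count:
            logger.warning(
                "sliding-window correlation: %d undefined values "
                "(constant window segments) recorded as NaN", nan_count
            )
        return out


def sliding_window_correlation(
    ts: RoiTimeSeries, window_length: int, method: str = "spearman"
) -> EdgeSeries:
    """Windowed correlation trajectories for every node pair of a subject.

    Thin wrapper over :class:`SlidingWindowConnectivity` that attaches the
    edge index and metadata.  See the class for semantics.
    """
    est = SlidingWindowConnectivity(window_length=window_length, method=method)
    values = est.fit(ts.values).transform(ts.values)
    logger.info(
        "connectivity: %d nodes, %d edges, %d windows (w=%d, %s), %d NaN",
        ts.n_nodes, values.shape[0], values.shape[1], window_length, method,
        est.nan_count_,
    )
    return EdgeSeries(
        values=values,
        window_length=window_length,
        method=method,
        edge_index=est.edge_index_,
        node_ids=ts.node_ids,
    )
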