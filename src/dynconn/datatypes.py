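"""Core data containers for the dynamic-connectivity pipeline.

The central object is the edge time-series: for ``N`` node (ROI) signals the
``E = N(N-1)/2`` unordered node pairs each carry one windowed-correlation
trajectory of length ``W = T - w + 1``.  Containers are thin, validated
wrappers around numpy arrays; edge ordering is always upper-triangle
row-major with ``i < j`` (0-based).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "RoiTimeSeries",
    "EdgeSeries",
    "EdgeSummary",
    "BinaryEdgeSeries",
    "NodePartition",
    "ScalingResult",
    "ContrastResult",
    "edge_pairs",
    "n_edges",
]


def n_edges(n_nodes: int) -> int:
    """Number of unordered node pairs among ``n_nodes`` nodes."""
    return n_nodes * (n_nodes - 1) // 2


def edge_pairs(n_nodes: int) -> np.ndarray:
    """Upper-triangle row-major edge index, shape ``(E, 2)`` with ``i < j``.

    This fixed ordering is shared by every container so that per-edge rows
    line up across stages without an explicit join.
    """
    iu = np.triu_indices(n_nodes, k=1)
    return np.column_stack(iu).astype(np.int64)


def _as_float_matrix(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be 2-D, got shape {arr.shape}")
    return arr


@dataclass
class RoiTimeSeries:
    """Per-subject node signal matrix.

    Parameters
    ----------
    values : ndarray, shape (n_nodes, n_timepoints)
        Signal intensity per node and sample; arbitrary units.
    node_ids : sequence of str
        One identifier per node (row).
    tr : float
        Sampling interval (repetition time) in seconds.
    """

    values: np.ndarray
    node_ids: Sequence[str]
    tr: float = 2.0

    def __post_init__(self) -> None:
        self.values = _as_float_matrix(self.values, "values")
        n, t = self.values.shape
        if n < 2:
            raise ValueError(f"need at least 2 nodes, got {n}")
        if t < 2:
            raise ValueError(f"need at least 2 timepoints, got {t}")
        self.node_ids = [str(x) for x in self.node_ids]
        if len(self.node_ids) != n:
            raise ValueError(
                f"{len(self.node_ids)} node_ids for {n} rows"
            )
        if len(set(self.node_ids)) != n:
            raise ValueError("duplicate node_ids")
        if not np.isfinite(self.values).all():
            raise ValueError("values contain missing/non-finite entries")
        if self.tr <= 0:
            raise ValueError(f"tr must be positive, got {self.tr}")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


@dataclass
class EdgeSeries:
    """Edge-major windowed-correlation matrix, shape ``(E, W)``.

    ``values[e, t]`` is the correlation of edge ``e`` over the window
    covering samples ``[t, t + window_length)``.  Undefined correlations
    (a constant segment inside a window) are stored as NaN and excluded,
    with counts, from all downstream summaries.
    """

    values: np.ndarray
    window_length: int
    method: str
    edge_index: np.ndarray
    node_ids: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.values = _as_float_matrix(self.values, "values")
        self.edge_index = np.asarray(self.edge_index, dtype=np.int64)
        if self.edge_index.ndim != 2 or self.edge_index.shape[1] != 2:
            raise ValueError("edge_index must have shape (E, 2)")
        if self.edge_index.shape[0] != self.values.shape[0]:
            raise ValueError("edge_index length must match number of rows")
        if np.any(self.edge_index[:, 0] >= self.edge_index[:, 1]):
            raise ValueError("edge_index must satisfy i < j")
        if self.method not in ("spearman", "pearson"):
            raise ValueError(f"unknown method {self.method!r}")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1 - 1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("correlation values outside [-1, 1]")

    @property
    def n_edges(self) -> int:
        return self.values.shape[0]

    @property
    def n_windows(self) -> int:
        return self.values.shape[1]

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    @property
    def n_nodes(self) -> int:
        return int(self.edge_index.max()) + 1

    def matrix_at(self, window: int) -> np.ndarray:
        """Full symmetric correlation matrix (unit diagonal) at one window."""
        n = self.n_nodes
        mat = np.eye(n)
        i, j = self.edge_index.T
        mat[i, j] = self.values[:, window]
        mat[j, i] = self.values[:, window]
        return mat


@dataclass
class EdgeSummary:
    """Per-edge temporal mean and (unbiased) variance of an edge series."""

    edge_index: np.ndarray
    mean: np.ndarray
    variance: np.ndarray
    n_windows: np.ndarray

    def __post_init__(self) -> None:
        self.edge_index = np.asarray(self.edge_index, dtype=np.int64)
        self.mean = np.asarray(self.mean, dtype=float)
        self.variance = np.asarray(self.variance, dtype=float)
        self.n_windows = np.asarray(self.n_windows, dtype=np.int64)
        e = self.edge_index.shape[0]
        for name, arr in (("mean", self.mean), ("variance", self.variance),
                          ("n_windows", self.n_windows)):
            if arr.shape != (e,):
                raise ValueError(f"{name} must have shape ({e},)")
        if np.any(self.variance < -1e-12):
            raise ValueError("negative variance")

    @property
    def n_edges(self) -> int:
        return self.edge_index.shape[0]


@dataclass
class BinaryEdgeSeries:
    """Boolean edge-presence raster from one thresholding strategy.

    ``strategy`` is ``"magnitude"`` (global cutoff on the correlation value)
    or ``"variance"`` (per-edge cutoff at mean + k*SD of the edge's own
    trajectory); ``parameter`` is the cutoff c or multiplier k respectively.
    Missing source values map to absent; ``n_masked`` records how many.
    """

    present: np.ndarray
    strategy: str
    parameter: float
    edge_index: np.ndarray
    n_masked: int = 0

    def __post_init__(self) -> None:
        self.present = np.asarray(self.present, dtype=bool)
        if self.present.ndim != 2:
            raise ValueError("present must be 2-D")
        if self.strategy not in ("magnitude", "variance"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        self.edge_index = np.asarray(self.edge_index, dtype=np.int64)

    @property
    def density(self) -> float:
        """Global fraction of present (edge, window) cells."""
        return float(self.present.mean())


@dataclass
class NodePartition:
    """Node -> network-label assignment (e.g. resting-state networks)."""

    labels: Sequence[str]
    node_ids: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.labels = [str(x) for x in self.labels]
        if not self.labels:
            raise ValueError("empty partition")
        if self.node_ids is not None:
            self.node_ids = [str(x) for x in self.node_ids]
            if len(self.node_ids) != len(self.labels):
                raise ValueError("node_ids/labels length mismatch")

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def networks(self) -> list[str]:
        """Distinct labels in first-appearance order (display order)."""
        seen: dict[str, None] = {}
        for lab in self.labels:
            seen.setdefault(lab, None)
        return list(seen)


@dataclass
class ScalingResult:
    """Spearman rank correlation between per-edge means and variances."""

    rho: float
    p_value: float
    n_edges: int
    method: str = "t-approximation"

    def to_dict(self) -> dict:
        return {"rho": self.rho, "p_value": self.p_value,
                "n_edges": self.n_edges, "method": self.method}


@dataclass
class ContrastResult:
    """Within- vs between-network variance contrast across subjects."""

    within_mean_variance: np.ndarray
    between_mean_variance: np.ndarray
    t_statistic: float
    p_value: float
    n_subjects: int
    paired: bool = True
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "within_mean_variance": list(map(float, self.within_mean_variance)),
            "between_mean_variance": list(map(float, self.between_mean_variance)),
            "t_statistic": self.t_statistic,
            "p_value": self.p_value,
            "n_subjects": self.n_subjects,
            "paired": self.paired,
            "degenerate": self.degenerate,
        }
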