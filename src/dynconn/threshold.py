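"""Binarizing edge trajectories into presence rasters.

Two strategies.  The magnitude strategy applies one global cutoff to the
correlation value itself, so it favours edges that are strongly correlated
throughout (within-network edges).  The variance strategy thresholds each
edge at its own temporal mean plus ``k`` standard deviations, so it marks
the moments an edge is unusually high for *that* edge, regardless of its
overall level — which favours fluctuating, lower-mean (between-network)
edges.  Adding a constant to a trajectory shifts its magnitude raster but
leaves its variance raster untouched; that location/scale contrast is the
operational difference between the strategies.

Both use strict inequality (">"), so a constant edge is never present
under the variance strategy.  Thresholds apply to signed correlations by
default; set ``absolute=True`` to threshold |r|.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import BinaryEdgeSeries, EdgeSeries

__all__ = [
    "MagnitudeThresholder",
    "VarianceThresholder",
    "magnitude_threshold",
    "variance_threshold",
    "presence_overlap",
    "OverlapSummary",
]

logger = logging.getLogger(__name__)


class _BaseThresholder(BaseEstimator, TransformerMixin):
    def fit(self, X, y=None):
        return self

    def _prep(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected an edges x windows matrix")
        self.n_masked_ = int(np.isnan(X).sum())
        if self.n_masked_:
            logger.warning(
                "thresholding: %d missing values mapped to absent",
                self.n_masked_,
            )
        return np.abs(X) if getattr(self, "absolute", False) else X


class MagnitudeThresholder(_BaseThresholder):
    """Presence iff the windowed correlation strictly exceeds a global cutoff.

    Parameters
    ----------
    cutoff : float
        Global correlation cutoff, in (-1, 1).
    absolute : bool
        Threshold ``|r|`` instead of the signed value.
    """

    def __init__(self, cutoff: float = 0.3, absolute: bool = False):
        self.cutoff = cutoff
        self.absolute = absolute

    def transform(self, X) -> np.ndarray:
        if not -1 < self.cutoff < 1:
            raise ValueError(f"cutoff must be in (-1, 1), got {self.cutoff}")
        X = self._prep(X)
        with np.errstate(invalid="ignore"):
            present = X > self.cutoff
        present[np.isnan(X)] = False
        return present


class VarianceThresholder(_BaseThresholder):
    """Presence iff an edge exceeds its own mean + k standard deviations.

    The mean and (sample, n-1) SD are computed per edge from that edge's
    own trajectory, NaNs excluded.  A zero-SD (constant) edge has no
    present windows.

    Parameters
    ----------
    k : float
        SD multiplier, > 0.  The field's common choice is 1.
    absolute : bool
        Threshold ``|r|`` instead of the signed value.
    """

    def __init__(self, k: float = 1.0, absolute: bool = False):
        self.k = k
        self.absolute = absolute

    def transform(self, X) -> np.ndarray:
        if self.k <= 0:
            raise ValueError(f"k must be positive, got {self.k}")
        X = self._prep(X)
        ok = np.isfinite(X)
        if np.any(ok.sum(axis=1) < 2):
            raise ValueError("every edge needs >= 2 usable windows")
        mu = np.nanmean(X, axis=1, keepdims=True)
        sd = np.sqrt(np.nanvar(X, axis=1, ddof=1, keepdims=True))
        n_const = int(np.sum(sd == 0))
        if n_const:
            logger.info(
                "variance threshold: %d constant edge(s), no windows present",
                n_const,
            )
        with np.errstate(invalid="ignore"):
            present = X > mu + self.k * sd
        present[~ok] = False
        return present


def magnitude_threshold(es: EdgeSeries, cutoff: float,
                        absolute: bool = False) -> BinaryEdgeSeries:
    """Global-cutoff binarization of an edge series (strict ``r > cutoff``)."""
    est = MagnitudeThresholder(cutoff=cutoff, absolute=absolute)
    present = est.fit(es.values).transform(es.values)
    return BinaryEdgeSeries(
        present=present, strategy="magnitude", parameter=float(cutoff),
        edge_index=es.edge_index, n_masked=est.n_masked_,
    )


def variance_threshold(es: EdgeSeries, k: float = 1.0,
                       absolute: bool = False) -> BinaryEdgeSeries:
    """Per-edge mean + k*SD binarization of an edge series."""
    est = VarianceThresholder(k=k, absolute=absolute)
    present = est.fit(es.values).transform(es.values)
    return BinaryEdgeSeries(
        present=present, strategy="variance", parameter=float(k),
        edge_index=es.edge_index, n_masked=est.n_masked_,
    )


@dataclass
class OverlapSummary:
    """Agreement between two presence rasters of the same shape."""

    jaccard: np.ndarray       # per-edge Jaccard of present sets
    density_a: float
    density_b: float

    @property
    def mean_jaccard(self) -> float:
        return float(np.mean(self.jaccard))


def presence_overlap(a: BinaryEdgeSeries, b: BinaryEdgeSeries) -> OverlapSummary:
    """Per-edge Jaccard index between two rasters, plus global densities.

    Two edges that are absent everywhere in both rasters agree perfectly
    and get Jaccard 1.
    """
    if a.present.shape != b.present.shape:
        raise ValueError(
            f"shape mismatch: {a.present.shape} vs {b.present.shape}"
        )
    inter = np.logical_and(a.present, b.present).sum(axis=1)
    union = np.logical_or(a.present, b.present).sum(axis=1)
    jac = np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    return OverlapSummary(
        jaccard=jac, density_a=a.density, density_b=b.density
    )
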