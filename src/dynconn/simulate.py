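"""Synthetic connectivity data with analytically known ground truth.

Two generators:

* :func:`generate_sinusoid` — an idealized single-edge connectivity
  trajectory ``v(t) = m + A sin(2*pi*t/P + phi)``, used to contrast the two
  thresholding strategies on a pair of anti-phase curves (a high-mean /
  low-variance edge vs a zero-mean / high-variance edge).

* :func:`generate_cohort` — multi-subject node time-series with a block
  (network) structure and a prescribed time-varying correlation.  Node
  ``i`` in block ``k`` is the mixture

      x_i(t) = a_k(t) g_k(t) + b(t) h(t) + sqrt(1 - a_k(t)^2 - b(t)^2) e_i(t)

  of a shared block latent ``g_k``, a global latent ``h`` and private
  noise ``e_i``, all independent, zero-mean, unit-variance.  The implied
  instantaneous correlation is then exactly ``a_k(t)^2 + b(t)^2`` for two
  nodes of block ``k`` and ``b(t)^2`` across blocks, which is returned as
  :class:`GroundTruth` so estimator output can be checked against a closed
  form.  Latents are optionally bandpass-filtered white noise
  (default 0.008-0.1 Hz), giving the slow autocorrelation characteristic
  of hemodynamic signals without modelling a response function.

The default cohort has constant, high within-block coupling and a slowly
fluctuating, low global coupling: within-block edges then have a high
temporal-mean / low-variance correlation and between-block edges the
opposite, the regime in which magnitude- and variance-based edge selection
disagree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal

from .datatypes import NodePartition, RoiTimeSeries

__all__ = [
    "SinusoidSpec",
    "Trajectory",
    "BlockCohortSpec",
    "GroundTruth",
    "Cohort",
    "generate_sinusoid",
    "generate_cohort",
    "demo_sinusoid_pair",
    "window_average",
]

_EPS = 1e-9


@dataclass(frozen=True)
class SinusoidSpec:
    """Sinusoidal correlation trajectory: ``m + A sin(2*pi*t/P + phi)``.

    ``|mean| + amplitude`` must not exceed 1 so every value is a valid
    correlation.
    """

    mean: float = 0.0
    amplitude: float = 0.2
    period: float = 60.0
    phase: float = 0.0
    n_samples: int = 240

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if abs(self.mean) + self.amplitude > 1 + _EPS:
            raise ValueError(
                f"|mean| + amplitude = {abs(self.mean) + self.amplitude} > 1: "
                "values would leave [-1, 1]"
            )
        if self.period <= 0:
            raise ValueError("period must be > 0")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


def generate_sinusoid(spec: SinusoidSpec) -> np.ndarray:
    """Sample the trajectory at integer times ``t = 0 .. n_samples - 1``."""
    t = np.arange(spec.n_samples)
    return spec.mean + spec.amplitude * np.sin(
        2 * np.pi * t / spec.period + spec.phase
    )


def demo_sinusoid_pair(n_samples: int = 240,
                       period: float = 60.0) -> tuple[np.ndarray, np.ndarray]:
    """The worked-example pair of anti-phase connectivity trajectories.

    S1: mean 0.26, amplitude 0.05 (high level, small fluctuation).
    S2: mean 0,    amplitude 0.2, phase pi (low level, large fluctuation;
    spans exactly -0.2 .. 0.2 when the period divides into quarters on the
    sample grid).
    """
    s1 = generate_sinusoid(SinusoidSpec(0.26, 0.05, period, 0.0, n_samples))
    s2 = generate_sinusoid(SinusoidSpec(0.0, 0.2, period, math.pi, n_samples))
    return s1, s2


@dataclass(frozen=True)
class Trajectory:
    """A coupling-strength time-course, constant or sinusoidal, in [0, 1]."""

    kind: str = "constant"            # "constant" | "sinusoid"
    mean: float = 0.5
    amplitude: float = 0.0
    period: float = 200.0
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "sinusoid"):
            raise ValueError(f"unknown trajectory kind {self.kind!r}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        lo = self.mean - (self.amplitude if self.kind == "sinusoid" else 0)
        hi = self.mean + (self.amplitude if self.kind == "sinusoid" else 0)
        if lo < -_EPS or hi > 1 + _EPS:
            raise ValueError(
                f"trajectory range [{lo}, {hi}] leaves [0, 1]"
            )
        if self.kind == "sinusoid" and self.period <= 0:
            raise ValueError("period must be > 0")

    def values(self, n_samples: int) -> np.ndarray:
        t = np.arange(n_samples)
        if self.kind == "constant":
            return np.full(n_samples, float(self.mean))
        return self.mean + self.amplitude * np.sin(
            2 * np.pi * t / self.period + self.phase
        )

    def to_dict(self) -> dict:
        return {"kind": self.kind, "mean": self.mean,
                "amplitude": self.amplitude, "period": self.period,
                "phase": self.phase}


def _default_block_labels(n_nodes: int = 40, n_blocks: int = 4) -> list[str]:
    if n_nodes % n_blocks:
        raise ValueError("n_nodes must be divisible by n_blocks for the "
                         "default labelling")
    size = n_nodes // n_blocks
    return [f"N{k + 1}" for k in range(n_blocks) for _ in range(size)]


@dataclass
class BlockCohortSpec:
    """Study conditions for a synthetic multi-subject cohort.

    Defaults emulate a short resting-state session: 240 samples at
    TR = 2 s, 40 nodes in 4 networks of 10, constant within-block coupling
    a = 0.8 and a slow global coupling b(t) = 0.3 + 0.2 sin(2*pi*t/200).
    The constraint ``a_k(t)^2 + b(t)^2 <= 1`` keeps the private-noise
    variance non-negative at every sample.
    """

    n_subjects: int = 20
    n_nodes: int = 40
    block_labels: Sequence[str] | None = None
    n_timepoints: int = 240
    tr: float = 2.0
    within_coupling: Trajectory | dict[str, Trajectory] = field(
        default_factory=lambda: Trajectory("constant", mean=0.8)
    )
    global_coupling: Trajectory = field(
        default_factory=lambda: Trajectory(
            "sinusoid", mean=0.3, amplitude=0.2, period=200.0
        )
    )
    latent_bandpass: tuple[float, float] | None = (0.008, 0.1)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.block_labels is None:
            self.block_labels = _default_block_labels(self.n_nodes)
        self.block_labels = [str(x) for x in self.block_labels]
        if len(self.block_labels) != self.n_nodes:
            raise ValueError("block_labels length must equal n_nodes")
        if self.n_subjects < 1:
            raise ValueError("need at least 1 subject")
        if self.n_nodes < 2:
            raise ValueError("need at least 2 nodes")
        if self.n_timepoints < 2:
            raise ValueError("need at least 2 timepoints")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        for lab in self.blocks:
            if self.block_labels.count(lab) < 2:
                raise ValueError(f"block {lab!r} has fewer than 2 nodes")
        if self.latent_bandpass is not None:
            lo, hi = self.latent_bandpass
            nyq = 0.5 / self.tr
            if not 0 < lo < hi < nyq:
                raise ValueError(
                    f"bandpass ({lo}, {hi}) Hz invalid for Nyquist {nyq} Hz"
                )
        # noise variance must stay non-negative at every sample
        b2 = self.global_coupling.values(self.n_timepoints) ** 2
        for lab in self.blocks:
            a2 = self.coupling_for(lab).values(self.n_timepoints) ** 2
            worst = float(np.max(a2 + b2))
            if worst > 1 + _EPS:
                raise ValueError(
                    f"a_k(t)^2 + b(t)^2 reaches {worst:.4f} > 1 for block "
                    f"{lab!r}: private-noise variance would be negative"
                )

    @property
    def blocks(self) -> list[str]:
        seen: dict[str, None] = {}
        for lab in self.block_labels:
            seen.setdefault(lab, None)
        return list(seen)

    def coupling_for(self, block: str) -> Trajectory:
        if isinstance(self.within_coupling, dict):
            return self.within_coupling[block]
        return self.within_coupling

    def to_dict(self) -> dict:
        wc = self.within_coupling
        wc_dict = ({k: v.to_dict() for k, v in wc.items()}
                   if isinstance(wc, dict) else wc.to_dict())
        return {
            "n_subjects": self.n_subjects,
            "n_nodes": self.n_nodes,
            "block_labels": list(self.block_labels),
            "n_timepoints": self.n_timepoints,
            "tr": self.tr,
            "within_coupling": wc_dict,
            "global_coupling": self.global_coupling.to_dict(),
            "latent_bandpass": (list(self.latent_bandpass)
                                if self.latent_bandpass else None),
            "seed": self.seed,
        }


@dataclass
class GroundTruth:
    """Model-implied instantaneous correlations of a block cohort.

    ``within_corr[k][t] = a_k(t)^2 + b(t)^2`` for two nodes of block ``k``;
    ``between_corr[t] = b(t)^2`` for nodes of different blocks.
    """

    within_corr: dict[str, np.ndarray]
    between_corr: np.ndarray

    def edge_truth(self, edge_index: np.ndarray,
                   labels: Sequence[str]) -> np.ndarray:
        """Per-edge truth trajectories, shape ``(E, T)``."""
        edge_index = np.asarray(edge_index)
        out = np.empty((edge_index.shape[0], self.between_corr.size))
        for e, (i, j) in enumerate(edge_index):
            li, lj = labels[int(i)], labels[int(j)]
            out[e] = self.within_corr[li] if li == lj else self.between_corr
        return out


@dataclass
class Cohort:
    subjects: list[RoiTimeSeries]
    ground_truth: GroundTruth
    partition: NodePartition
    spec: BlockCohortSpec


def _standardize(x: np.ndarray, axis: int = -1) -> np.ndarray:
    x = x - x.mean(axis=axis, keepdims=True)
    sd = x.std(axis=axis, keepdims=True)
    return x / np.where(sd == 0, 1.0, sd)


def _latents(rng: np.random.Generator, n: int, t: int,
             band: tuple[float, float] | None, tr: float) -> np.ndarray:
    """n independent zero-mean unit-variance latent series of length t."""
    x = rng.standard_normal((n, t))
    if band is not None:
        sos = signal.butter(2, band, btype="bandpass", fs=1.0 / tr,
                            output="sos")
        x = signal.sosfiltfilt(sos, x, axis=-1)
    return _standardize(x)


def generate_cohort(spec: BlockCohortSpec) -> Cohort:
    """Draw the cohort; bit-identical for identical specs (same seed)."""
    t = spec.n_timepoints
    blocks = spec.blocks
    b = spec.global_coupling.values(t)
    a = {lab: spec.coupling_for(lab).values(t) for lab in blocks}

    truth = GroundTruth(
        within_corr={lab: a[lab] ** 2 + b ** 2 for lab in blocks},
        between_corr=b ** 2,
    )

    labels = list(spec.block_labels)
    node_ids = [f"node{idx:03d}" for idx in range(spec.n_nodes)]
    noise_sd = {
        lab: np.sqrt(np.clip(1.0 - a[lab] ** 2 - b ** 2, 0.0, None))
        for lab in blocks
    }

    streams = np.random.SeedSequence(spec.seed).spawn(spec.n_subjects)
    subjects = []
    for ss in streams:
        rng = np.random.default_rng(ss)
        h = _latents(rng, 1, t, spec.latent_bandpass, spec.tr)[0]
        g = {lab: lat for lab, lat in zip(
            blocks, _latents(rng, len(blocks), t, spec.latent_bandpass,
                             spec.tr))}
        eps = _latents(rng, spec.n_nodes, t, spec.latent_bandpass, spec.tr)
        x = np.empty((spec.n_nodes, t))
        for i, lab in enumerate(labels):
            x[i] = a[lab] * g[lab] + b * h + noise_sd[lab] * eps[i]
        subjects.append(RoiTimeSeries(_standardize(x), node_ids, tr=spec.tr))

    return Cohort(
        subjects=subjects,
        ground_truth=truth,
        partition=NodePartition(labels=labels, node_ids=node_ids),
        spec=spec,
    )


def window_average(trajectory: np.ndarray, window_length: int) -> np.ndarray:
    """Mean of a trajectory over each sliding window (matches the
    windowed-correlation grid: output length ``T - w + 1``)."""
    trajectory = np.asarray(trajectory, dtype=float)
    if window_length > trajectory.size:
        raise ValueError("window longer than trajectory")
    kernel = np.ones(window_length) / window_length
    return np.convolve(trajectory, kernel, mode="valid")
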