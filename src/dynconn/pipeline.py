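"""End-to-end orchestration: simulate -> connect -> stats -> threshold -> rsn.

A run is driven by a :class:`RunConfig` (YAML-loadable, CLI-overridable)
and leaves behind a manifest recording the config hash, seed, per-stage
output hashes, missing-value counts and timings, so identical config +
seed gives identical output hashes.  Stages communicate only through the
documented file formats: deleting downstream outputs and re-running
reproduces them bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import io as dio
from .connectivity import seconds_to_samples, sliding_window_correlation
from .datatypes import RoiTimeSeries
from .rsn import plot_variance_matrix, variance_contrast, variance_matrix
from .simulate import BlockCohortSpec, Trajectory, generate_cohort
from .stats import group_average, mean_variance_scaling, summarize_edges
from .threshold import magnitude_threshold, variance_threshold

__all__ = ["RunConfig", "run_pipeline", "sweep"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    ``input_dir`` may point at an existing cohort directory (subject TSVs
    plus ``partition.tsv``); when None, a synthetic cohort is generated
    from the ``simulate`` block.
    """

    out_dir: str = "dynconn_run"
    input_dir: str | None = None
    window_seconds: float = 90.0
    tr: float = 2.0
    method: str = "spearman"
    thresholds: list[float] = field(default_factory=lambda: [0.3, 0.2, 0.15])
    k: float = 1.0
    seed: int = 0
    simulate: dict = field(default_factory=dict)
    write_edges: bool = False
    make_figures: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def validate(self) -> None:
        seconds_to_samples(self.window_seconds, self.tr)  # integral check
        if self.input_dir is not None and not Path(self.input_dir).is_dir():
            raise ValueError(f"input_dir {self.input_dir!r} not found")

    def to_dict(self) -> dict:
        return asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _cohort_spec(cfg: RunConfig) -> BlockCohortSpec:
    sim = dict(cfg.simulate)
    n_blocks = sim.pop("n_blocks", None)
    for key in ("within_coupling", "global_coupling"):
        if key in sim and isinstance(sim[key], dict):
            sim[key] = Trajectory(**sim[key])
    spec = BlockCohortSpec(seed=cfg.seed, tr=cfg.tr, **sim)
    if n_blocks is not None:
        n = spec.n_nodes
        if n % n_blocks:
            raise ValueError("n_nodes must be divisible by n_blocks")
        size = n // n_blocks
        spec = BlockCohortSpec(
            **{**spec.to_dict(),
               "within_coupling": spec.within_coupling,
               "global_coupling": spec.global_coupling,
               "latent_bandpass": spec.latent_bandpass,
               "block_labels": [f"N{k + 1}" for k in range(n_blocks)
                                for _ in range(size)]})
    return spec


def _load_subjects(input_dir: Path, tr: float):
    paths = sorted(p for p in input_dir.glob("subject_*.tsv"))
    if not paths:
        raise ValueError(f"no subject_*.tsv files in {input_dir}")
    subjects = [dio.read_roi_table(p, tr=tr) for p in paths]
    partition = dio.read_partition(input_dir / "partition.tsv")
    return subjects, partition


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order; returns (and writes) the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "stages": {},
        "outputs": {},
    }
    outputs: dict[str, str] = manifest["outputs"]

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                info = fn() or {}
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            info["seconds"] = round(time.perf_counter() - t0, 3)
            manifest["stages"][name] = info
            logger.info("stage %s: %s", name, info)
            return info
        return deco

    state: dict = {}

    @stage("input")
    def _input():
        if config.input_dir is None:
            cohort = generate_cohort(_cohort_spec(config))
            cohort_dir = dio.write_cohort(cohort, out / "cohort")
            for p in sorted(cohort_dir.iterdir()):
                outputs[f"cohort/{p.name}"] = _sha256(p)
            state["subjects"] = cohort.subjects
            state["partition"] = cohort.partition
            return {"source": "synthetic",
                    "n_subjects": len(cohort.subjects)}
        subjects, partition = _load_subjects(Path(config.input_dir),
                                             config.tr)
        state["subjects"], state["partition"] = subjects, partition
        return {"source": config.input_dir, "n_subjects": len(subjects)}

    @stage("connect")
    def _connect():
        w = seconds_to_samples(config.window_seconds, config.tr)
        edge_series = [sliding_window_correlation(s, w, config.method)
                       for s in state["subjects"]]
        state["edges"] = edge_series
        if config.write_edges:
            edir = out / "edges"
            edir.mkdir(exist_ok=True)
            for i, es in enumerate(edge_series, start=1):
                p = dio.write_edge_series(es, edir / f"subject_{i:02d}.tsv")
                outputs[f"edges/{p.name}"] = _sha256(p)
        return {"window_samples": w,
                "n_edges": edge_series[0].n_edges,
                "n_windows": edge_series[0].n_windows,
                "n_missing": int(sum(e.n_missing for e in edge_series))}

    @stage("stats")
    def _stats():
        summaries = [summarize_edges(es) for es in state["edges"]]
        state["summaries"] = summaries
        sdir = out / "summaries"
        sdir.mkdir(exist_ok=True)
        for i, s in enumerate(summaries, start=1):
            p = dio.write_summary(s, sdir / f"subject_{i:02d}.tsv")
            outputs[f"summaries/{p.name}"] = _sha256(p)
        group = group_average(summaries)
        state["group"] = group
        p = dio.write_summary(group, out / "group_summary.tsv")
        outputs["group_summary.tsv"] = _sha256(p)
        scaling = mean_variance_scaling(group)
        p = out / "scaling.json"
        p.write_text(json.dumps(scaling.to_dict(), indent=1))
        outputs["scaling.json"] = _sha256(p)
        return {"rho": scaling.rho, "p_value": scaling.p_value}

    @stage("threshold")
    def _threshold():
        es = state["edges"][0]  # demo rasters on the first subject
        densities = {}
        for c in config.thresholds:
            r = magnitude_threshold(es, c)
            densities[f"magnitude_{c}"] = r.density
        rv = variance_threshold(es, config.k)
        densities[f"variance_k{config.k}"] = rv.density
        p = out / "raster_densities.json"
        p.write_text(json.dumps(densities, indent=1))
        outputs["raster_densities.json"] = _sha256(p)
        return densities

    @stage("rsn")
    def _rsn():
        contrast = variance_contrast(state["summaries"], state["partition"])
        p = out / "contrast.json"
        p.write_text(json.dumps(contrast.to_dict(), indent=1))
        outputs["contrast.json"] = _sha256(p)
        mat, order = variance_matrix(state["group"], state["partition"])
        np.savetxt(out / "variance_matrix.tsv", mat, delimiter="\t",
                   fmt="%.17g")
        outputs["variance_matrix.tsv"] = _sha256(out / "variance_matrix.tsv")
        if config.make_figures:
            plot_variance_matrix(state["group"], state["partition"],
                                 str(out / "variance_matrix.png"))
        return {"t_statistic": contrast.t_statistic,
                "p_value": contrast.p_value}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def sweep(config: RunConfig,
          windows_seconds: list[float] = (50.0, 90.0, 130.0),
          methods: list[str] = ("spearman", "pearson")) -> dict:
    """Robustness sweep: the scaling test across window lengths and
    correlation methods on one cohort.  Returns {"<sec>s_<method>":
    ScalingResult-dict}, also written to ``<out_dir>/sweep.json``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.input_dir is None:
        cohort = generate_cohort(_cohort_spec(config))
        subjects = cohort.subjects
    else:
        subjects, _ = _load_subjects(Path(config.input_dir), config.tr)
    results = {}
    for ws in windows_seconds:
        w = seconds_to_samples(ws, config.tr)
        for method in methods:
            summaries = [summarize_edges(sliding_window_correlation(s, w,
                                                                    method))
                         for s in subjects]
            res = mean_variance_scaling(group_average(summaries))
            results[f"{ws:g}s_{method}"] = res.to_dict()
            logger.info("sweep %gs %s: rho=%.4f", ws, method, res.rho)
    (out / "sweep.json").write_text(json.dumps(results, indent=1))
    return results
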