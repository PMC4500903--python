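"""Reading and writing the pipeline's plain-text artifact formats.

Node tables are TSV (or CSV) with a ``node_id`` first column and one
column per sample; partitions are two-column TSV (node_id, label); edge
series / summaries / rasters carry ``edge_i``/``edge_j`` index columns so
files are self-describing.  Round trips are value-exact (floats are
written with repr precision).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    BinaryEdgeSeries,
    EdgeSeries,
    EdgeSummary,
    NodePartition,
    RoiTimeSeries,
)
from .simulate import Cohort

__all__ = [
    "read_roi_table", "write_roi_table",
    "read_partition", "write_partition",
    "read_edge_series", "write_edge_series",
    "read_summary", "write_summary",
    "write_raster", "read_raster",
    "write_cohort",
]

_FLOAT_FMT = "%.17g"


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def write_roi_table(ts: RoiTimeSeries, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(ts.values, index=pd.Index(ts.node_ids, name="node_id"),
                      columns=np.arange(ts.n_timepoints))
    df.to_csv(path, sep=_sep_for(path), float_format=_FLOAT_FMT)
    return path


def read_roi_table(path: str | Path, tr: float = 2.0) -> RoiTimeSeries:
    """Parse a nodes x time table; TSV or CSV decided by suffix.

    Ragged rows, non-numeric or missing cells and duplicate node IDs are
    reported with their row/column location.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0,
                     float_precision="round_trip")
    node_ids = [str(x) for x in df.index]
    dup = pd.Index(node_ids).duplicated()
    if dup.any():
        rows = list(np.nonzero(dup)[0] + 2)  # +2: header + 1-based
        raise ValueError(f"{path}: duplicate node IDs at line(s) {rows}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric cell ({exc})") from exc
    bad = ~np.isfinite(values)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: missing/non-finite cell at line {r + 2}, "
            f"column {df.columns[c]!r} (node {node_ids[r]!r})"
        )
    return RoiTimeSeries(values=values, node_ids=node_ids, tr=tr)


def write_partition(partition: NodePartition, path: str | Path) -> Path:
    path = Path(path)
    ids = partition.node_ids or [f"node{i:03d}"
                                 for i in range(partition.n_nodes)]
    pd.DataFrame({"node_id": ids, "label": list(partition.labels)}).to_csv(
        path, sep="\t", index=False)
    return path


def read_partition(path: str | Path) -> NodePartition:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected node_id<TAB>label columns")
    if df.iloc[:, 1].isna().any():
        row = int(df.iloc[:, 1].isna().idxmax()) + 2
        raise ValueError(f"{path}: missing label at line {row}")
    return NodePartition(labels=list(df.iloc[:, 1]),
                         node_ids=list(df.iloc[:, 0]))


def write_edge_series(es: EdgeSeries, path: str | Path) -> Path:
    """Wide TSV (edge_i, edge_j, one column per window) + JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame(es.values, columns=np.arange(es.n_windows))
    df.insert(0, "edge_i", es.edge_index[:, 0])
    df.insert(1, "edge_j", es.edge_index[:, 1])
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    sidecar = {
        "window_length": es.window_length,
        "method": es.method,
        "n_missing": es.n_missing,
        "node_ids": list(es.node_ids) if es.node_ids else None,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1))
    return path


def read_edge_series(path: str | Path) -> EdgeSeries:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    edge_index = df[["edge_i", "edge_j"]].to_numpy(dtype=np.int64)
    values = df.drop(columns=["edge_i", "edge_j"]).to_numpy(dtype=float)
    return EdgeSeries(values=values, window_length=meta["window_length"],
                      method=meta["method"], edge_index=edge_index,
                      node_ids=meta.get("node_ids"))


def write_summary(summary: EdgeSummary, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({
        "edge_i": summary.edge_index[:, 0],
        "edge_j": summary.edge_index[:, 1],
        "mean": summary.mean,
        "variance": summary.variance,
        "n_windows": summary.n_windows,
    }).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return path


def read_summary(path: str | Path) -> EdgeSummary:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return EdgeSummary(
        edge_index=df[["edge_i", "edge_j"]].to_numpy(dtype=np.int64),
        mean=df["mean"].to_numpy(dtype=float),
        variance=df["variance"].to_numpy(dtype=float),
        n_windows=df["n_windows"].to_numpy(dtype=np.int64),
    )


def write_raster(raster: BinaryEdgeSeries, path: str | Path,
                 long_format: bool = False) -> Path:
    path = Path(path)
    if long_format:
        e, w = np.nonzero(np.ones_like(raster.present))
        pd.DataFrame({
            "edge_i": raster.edge_index[e, 0],
            "edge_j": raster.edge_index[e, 1],
            "window": w,
            "present": raster.present[e, w].astype(int),
        }).to_csv(path, sep="\t", index=False)
    else:
        df = pd.DataFrame(raster.present.astype(int),
                          columns=np.arange(raster.present.shape[1]))
        df.insert(0, "edge_i", raster.edge_index[:, 0])
        df.insert(1, "edge_j", raster.edge_index[:, 1])
        df.to_csv(path, sep="\t", index=False)
    sidecar = {"strategy": raster.strategy, "parameter": raster.parameter,
               "n_masked": raster.n_masked, "long_format": long_format}
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1))
    return path


def read_raster(path: str | Path) -> BinaryEdgeSeries:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    df = pd.read_csv(path, sep="\t")
    if meta.get("long_format"):
        n_w = int(df["window"].max()) + 1
        edges = df[["edge_i", "edge_j"]].drop_duplicates().to_numpy(np.int64)
        lookup = {tuple(e): k for k, e in enumerate(map(tuple, edges))}
        present = np.zeros((len(edges), n_w), dtype=bool)
        for _, row in df.iterrows():
            present[lookup[(row.edge_i, row.edge_j)], int(row.window)] = \
                bool(row.present)
        edge_index = edges
    else:
        edge_index = df[["edge_i", "edge_j"]].to_numpy(np.int64)
        present = df.drop(columns=["edge_i", "edge_j"]).to_numpy(bool)
    return BinaryEdgeSeries(present=present, strategy=meta["strategy"],
                            parameter=meta["parameter"],
                            edge_index=edge_index,
                            n_masked=meta["n_masked"])


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """One TSV per subject + partition TSV + JSON sidecar with the spec."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for k, subj in enumerate(cohort.subjects, start=1):
        write_roi_table(subj, out_dir / f"subject_{k:02d}.tsv")
    write_partition(cohort.partition, out_dir / "partition.tsv")
    (out_dir / "spec.json").write_text(
        json.dumps(cohort.spec.to_dict(), indent=1))
    return out_dir
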