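"""Readers and writers for traces, metadata, ensembles and results.

Trace matrices are delimited text with one row per cell and one column
per time point.  A JSON metadata sidecar supplies the sampling interval,
the stimulus frame and optional per-cell calibration triplets.  Particle
ensembles, distance matrices, cluster labels and convergence reports are
plain CSV so every artifact survives text-only archiving.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from castates.convergence import ConvergenceReport
from castates.ensemble_analysis import EnsembleDistanceMatrix
from castates.fitting import ParameterEnsemble
from castates.model import PARAMETER_NAMES
from castates.preprocess import CalciumTrace

__all__ = [
    "read_traces",
    "write_traces",
    "write_ensemble",
    "read_ensemble",
    "write_distance_matrix",
    "read_distance_matrix",
    "write_convergence_reports",
    "write_labels",
]


def read_traces(path, metadata_path) -> tuple[list[CalciumTrace], list[str]]:
    """Load a trace matrix plus its metadata sidecar.

    Returns the list of valid traces and a list of human-readable
    messages for rows that were rejected (NaNs, non-numeric cells).
    Ragged rows or missing metadata keys raise.
    """
    path, metadata_path = Path(path), Path(metadata_path)
    meta = json.loads(metadata_path.read_text())
    for key in ("dt", "stim_index"):
        if key not in meta:
            raise ValueError(f"metadata missing required key {key!r}")
    dt = float(meta["dt"])
    stim_index = int(meta["stim_index"])
    calib = meta.get("calibration")  # optional: cell_id -> [kd, fmin, fmax]
    cell_ids = meta.get("cell_ids")

    rows: list[list[str]] = []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sep = "\t" if "\t" in line else ","
            rows.append(line.split(sep))
    if not rows:
        raise ValueError(f"{path}: no data rows")
    width = len(rows[0])
    traces: list[CalciumTrace] = []
    problems: list[str] = []
    for i, row in enumerate(rows):
        cell_id = cell_ids[i] if cell_ids else f"cell{i:04d}"
        if len(row) != width:
            raise ValueError(
                f"{path}: row {i} has {len(row)} columns, expected {width}")
        try:
            values = np.array([float(v) for v in row])
        except ValueError:
            problems.append(f"row {i} ({cell_id}): non-numeric cell")
            continue
        if not np.all(np.isfinite(values)):
            problems.append(f"row {i} ({cell_id}): non-finite values")
            continue
        cal = None
        if calib is not None:
            entry = calib.get(cell_id) if isinstance(calib, dict) else calib
            if entry is not None:
                cal = (float(entry[0]), float(entry[1]), float(entry[2]))
        traces.append(CalciumTrace(values=values, dt=dt,
                                   stim_index=stim_index, cell_id=cell_id,
                                   calibration=cal))
    return traces, problems


def write_traces(traces, path, metadata_path) -> None:
    """Write traces and metadata in the format :func:`read_traces` expects."""
    path, metadata_path = Path(path), Path(metadata_path)
    traces = list(traces)
    if not traces:
        raise ValueError("no traces to write")
    dt = traces[0].dt
    stim_index = traces[0].stim_index
    n = len(traces[0])
    for t in traces:
        if len(t) != n or t.dt != dt or t.stim_index != stim_index:
            raise ValueError("all traces must share grid and stimulus frame")
    with path.open("w") as fh:
        for t in traces:
            fh.write("\t".join(repr(float(v)) for v in t.values) + "\n")
    meta = {
        "dt": dt,
        "stim_index": stim_index,
        "cell_ids": [t.cell_id for t in traces],
    }
    calib = {t.cell_id: list(t.calibration) for t in traces
             if t.calibration is not None}
    if calib:
        meta["calibration"] = calib
    metadata_path.write_text(json.dumps(meta, indent=1))


def write_ensemble(ensemble: ParameterEnsemble, path) -> None:
    """One row per particle: 17 named log10 parameters, score, run id."""
    df = pd.DataFrame(ensemble.particles, columns=list(PARAMETER_NAMES))
    df["score"] = ensemble.scores
    df["run_id"] = ensemble.run_id
    header = (f"# cell_id={ensemble.cell_id} run_id={ensemble.run_id} "
              f"epsilon_final={ensemble.epsilon_final!r} "
              f"fitted={ensemble.fitted} "
              f"iterations_used={ensemble.iterations_used} "
              f"total_proposals={ensemble.total_proposals}\n")
    with Path(path).open("w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def read_ensemble(path) -> ParameterEnsemble:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline()
        df = pd.read_csv(fh)
    meta = dict(tok.split("=", 1) for tok in header.lstrip("# ").split())
    return ParameterEnsemble(
        particles=df[list(PARAMETER_NAMES)].to_numpy(),
        scores=df["score"].to_numpy(),
        epsilon_final=float(meta["epsilon_final"]),
        cell_id=meta["cell_id"],
        run_id=int(meta["run_id"]),
        iterations_used=int(meta["iterations_used"]),
        fitted=meta["fitted"] == "True",
        total_proposals=int(meta["total_proposals"]))


def write_distance_matrix(dmat: EnsembleDistanceMatrix, path) -> None:
    pd.DataFrame(dmat.d, index=list(dmat.cell_ids),
                 columns=list(dmat.cell_ids)).to_csv(path)


def read_distance_matrix(path) -> EnsembleDistanceMatrix:
    df = pd.read_csv(path, index_col=0)
    return EnsembleDistanceMatrix(d=df.to_numpy(),
                                  cell_ids=tuple(df.index.astype(str)))


def write_convergence_reports(reports: dict[str, ConvergenceReport],
                              path) -> None:
    rows = [{"cell_id": cid, **vars(rep)} for cid, rep in reports.items()]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_labels(cell_ids, labels, path) -> None:
    pd.DataFrame({"cell_id": list(cell_ids),
                  "cluster": list(labels)}).to_csv(path, index=False)
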