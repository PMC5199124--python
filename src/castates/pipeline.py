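"""End-to-end pipeline orchestration.

Preprocess every cell, fit each twice with independent seeds, keep the
convergent cells, compute the pairwise ensemble distance matrix, cluster
and characterize.  Every stage failure is recorded in the attrition
summary instead of aborting the run, and the master seed pins all
randomness for exact reruns.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from castates import io as cio
from castates.convergence import test_convergence
from castates.ensemble_analysis import cluster, pairwise_distances
from castates.fitting import ScoreConfig, SMCConfig, fit_cell, score
from castates.preprocess import CalciumTrace, calibrate, noise_floor, smooth

log = logging.getLogger("castates")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything needed to rerun an analysis exactly."""

    traces_path: str
    metadata_path: str
    out_dir: str
    atp: float = 10.0
    filter_cutoff: float = 0.1
    score_config: ScoreConfig = field(default_factory=ScoreConfig)
    smc_config: SMCConfig = field(default_factory=SMCConfig)
    k_range: tuple[int, int] = (2, 10)
    seed: int = 0
    alpha: float = 0.05
    n_workers: int = 1

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=1, default=str)


def preprocess_cell(trace: CalciumTrace, cutoff: float,
                    score_cfg: ScoreConfig) -> tuple[CalciumTrace, float]:
    """Calibrate if needed, truncate, smooth, and compute the noise floor."""
    if trace.calibration is not None:
        kd, fmin, fmax = trace.calibration
        values = calibrate(trace.values, kd, fmin, fmax, clamp=True)
        trace = dataclasses.replace(trace, values=values, calibration=None)
    raw = trace.truncated()
    processed = smooth(raw, cutoff=cutoff)
    eps = noise_floor(raw, processed,
                      lambda a, b: score(a, b, score_cfg))
    return processed, eps


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full workflow; returns the attrition summary dict."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(cfg.to_json())

    traces, problems = cio.read_traces(cfg.traces_path, cfg.metadata_path)
    if not traces:
        raise ValueError("no valid traces in input")
    for msg in problems:
        log.warning("input: %s", msg)

    master = np.random.SeedSequence(cfg.seed)
    cell_seeds = master.spawn(len(traces))

    attempted, completed, convergent = [], [], []
    ensembles = {}
    reports = {}
    ensembles_dir = out / "ensembles"
    ensembles_dir.mkdir(exist_ok=True)

    for trace, seq in zip(traces, cell_seeds):
        cid = trace.cell_id
        attempted.append(cid)
        try:
            processed, eps = preprocess_cell(
                trace, cfg.filter_cutoff, cfg.score_config)
        except Exception as exc:  # recorded, not fatal
            log.warning("preprocess failed for %s: %s", cid, exc)
            continue
        run_seeds = seq.spawn(2)
        runs = []
        for run_id, rs in enumerate(run_seeds, start=1):
            ens = fit_cell(processed, eps, cfg.smc_config,
                           np.random.default_rng(rs), atp=cfg.atp,
                           score_cfg=cfg.score_config, run_id=run_id)
            cio.write_ensemble(ens, ensembles_dir / f"{cid}_run{run_id}.csv")
            runs.append(ens)
        if not all(r.fitted for r in runs):
            log.info("%s: fit did not reach epsilon_final", cid)
            continue
        completed.append(cid)
        rep = test_convergence(runs[0], runs[1], alpha=cfg.alpha,
                               seed=np.random.default_rng(seq.spawn(1)[0]))
        reports[cid] = rep
        if not rep.converged:
            log.info("%s: runs not convergent (p=%.3g)", cid, rep.p_value)
            continue
        convergent.append(cid)
        pooled = np.vstack([runs[0].particles, runs[1].particles])
        ensembles[cid] = dataclasses.replace(
            runs[0], particles=pooled,
            scores=np.concatenate([runs[0].scores, runs[1].scores]))

    cio.write_convergence_reports(reports, out / "convergence.csv")

    summary = {
        "attempted": len(attempted),
        "completed": len(completed),
        "convergent": len(convergent),
        "clustered": 0,
        "seed": cfg.seed,
    }
    if len(convergent) >= 3:
        dmat = pairwise_distances([ensembles[c] for c in convergent],
                                  cell_ids=convergent)
        cio.write_distance_matrix(dmat, out / "distance_matrix.csv")
        assign = cluster(dmat, range(cfg.k_range[0], cfg.k_range[1] + 1))
        cio.write_labels(convergent, assign.labels, out / "clusters.csv")
        summary["clustered"] = int(len(assign.labels))
        summary["k"] = int(assign.k)
        from castates.ensemble_analysis import characterize_clusters
        characterize_clusters([ensembles[c] for c in convergent],
                              assign.labels).to_csv(
            out / "cluster_characterization.csv")
    (out / "attrition.json").write_text(json.dumps(summary, indent=1))
    return summary
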