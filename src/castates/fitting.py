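"""Goodness-of-fit scoring and ABC-SMC posterior sampling.

The score is a sum of squared errors on trace values plus a weighted sum
of squared errors on first differences; the derivative term emphasizes
curve shape.  Posterior sampling is adaptive rejection: iteration zero
draws from a log10-uniform box prior, later iterations resample and
perturb the previous accepted population while the acceptance threshold
follows the previous population's score quantile, until every particle
beats the cell's own noise-floor threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from castates.model import PARAMETER_NAMES

__all__ = [
    "ScoreConfig",
    "SMCConfig",
    "ParameterEnsemble",
    "ThresholdUnreachable",
    "score",
    "rejection_sample",
    "smc_sample",
    "make_cell_scorer",
    "fit_cell",
]

N_PARAMS = len(PARAMETER_NAMES)


class ThresholdUnreachable(RuntimeError):
    """Acceptance rate fell below the floor within the proposal budget."""


@dataclass(frozen=True)
class ScoreConfig:
    """Weights of the goodness-of-fit score.

    ``deriv_weight`` scales the squared-error term on first differences
    relative to the value term.
    """

    deriv_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.deriv_weight < 0:
            raise ValueError("deriv_weight must be >= 0")


@dataclass(frozen=True)
class SMCConfig:
    """Knobs of the sequential ABC sampler."""

    n_particles: int = 500
    quantile: float = 0.9
    prior_halfwidth: float = 1.0
    max_iterations: int = 60
    kernel_scale: float = 1.0
    acceptance_floor: float = 1e-4
    proposal_batch: int = 256
    epsilon_prelim: float = math.inf

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise ValueError("n_particles must be >= 2")
        if not 0 < self.quantile < 1:
            raise ValueError("quantile must be in (0, 1)")
        if self.prior_halfwidth <= 0:
            raise ValueError("prior_halfwidth must be > 0")


@dataclass
class ParameterEnsemble:
    """Accepted-particle population approximating one cell's posterior."""

    particles: np.ndarray          # (n, 17) log10 fold-changes
    scores: np.ndarray             # (n,)
    epsilon_final: float
    cell_id: str = ""
    run_id: int = 1
    iterations_used: int = 0
    fitted: bool = True
    total_proposals: int = 0
    thresholds: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.particles = np.asarray(self.particles, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.particles.ndim != 2:
            raise ValueError("particles must be a 2-D array")
        if len(self.scores) != len(self.particles):
            raise ValueError("scores and particles length mismatch")

    def __len__(self) -> int:
        return len(self.particles)

    @property
    def acceptance_rate(self) -> float:
        if self.total_proposals == 0:
            return math.nan
        return len(self) * max(1, self.iterations_used) / self.total_proposals


def score(sim: np.ndarray, data: np.ndarray,
          cfg: ScoreConfig = ScoreConfig()) -> float:
    """Sum-squared error on values plus weighted SSE on first differences.

    Returns ``inf`` for a failed simulation (``sim is None`` or
    non-finite entries), which SMC treats as a rejection.
    """
    if sim is None:
        return math.inf
    sim = np.asarray(sim, dtype=float)
    data = np.asarray(data, dtype=float)
    if sim.shape != data.shape:
        raise ValueError(f"grid mismatch: {sim.shape} vs {data.shape}")
    if not np.all(np.isfinite(sim)):
        return math.inf
    resid = sim - data
    total = float(resid @ resid)
    if cfg.deriv_weight > 0:
        dresid = np.diff(sim) - np.diff(data)
        total += cfg.deriv_weight * float(dresid @ dresid)
    return total


def rejection_sample(propose: Callable[[np.random.Generator, int], np.ndarray],
                     score_theta: Callable[[np.ndarray], float],
                     epsilon: float, n: int, rng: np.random.Generator,
                     acceptance_floor: float = 1e-4,
                     batch: int = 256) -> tuple[np.ndarray, np.ndarray, int]:
    """Draw proposals until ``n`` particles score at or below ``epsilon``.

    Parameters
    ----------
    propose : callable(rng, m) -> (m, d) array
        Proposal generator.
    score_theta : callable(theta) -> float
        Simulate-and-score closure; ``inf`` marks a failed simulation.

    Returns
    -------
    (accepted, scores, total_proposals)

    Raises
    ------
    ThresholdUnreachable
        When the running acceptance rate drops below ``acceptance_floor``
        (checked after an initial grace budget).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    accepted: list[np.ndarray] = []
    acc_scores: list[float] = []
    proposals = 0
    grace = max(10_000, 10 * n)
    while len(accepted) < n:
        thetas = propose(rng, batch)
        for theta in thetas:
            proposals += 1
            s = score_theta(theta)
            if s <= epsilon:
                accepted.append(np.array(theta, dtype=float))
                acc_scores.append(s)
                if len(accepted) == n:
                    break
        if len(accepted) < n and proposals > grace:
            rate = len(accepted) / proposals
            if rate < acceptance_floor:
                raise ThresholdUnreachable(
                    f"acceptance rate {rate:.2e} below floor "
                    f"{acceptance_floor:.0e} after {proposals} proposals "
                    f"(epsilon={epsilon:.4g})")
    return np.array(accepted), np.array(acc_scores), proposals


def _prior_proposer(halfwidth: float, d: int = N_PARAMS):
    def propose(rng: np.random.Generator, m: int) -> np.ndarray:
        return rng.uniform(-halfwidth, halfwidth, size=(m, d))
    return propose


def _kernel_proposer(population: np.ndarray, halfwidth: float,
                     kernel_scale: float):
    """Resample a previous particle, perturb with a Gaussian kernel.

    Kernel SD per component = sqrt(kernel_scale * 2 * var) of the
    previous population.  Proposals outside the prior box are re-drawn,
    never clipped.
    """
    sd = np.sqrt(kernel_scale * 2.0 * np.var(population, axis=0))
    sd = np.maximum(sd, 1e-9)

    def propose(rng: np.random.Generator, m: int) -> np.ndarray:
        out = np.empty((m, population.shape[1]))
        filled = 0
        while filled < m:
            k = m - filled
            picks = population[rng.integers(0, len(population), size=k)]
            cand = picks + rng.normal(scale=sd, size=picks.shape)
            ok = np.all(np.abs(cand) <= halfwidth, axis=1)
            good = cand[ok]
            out[filled:filled + len(good)] = good
            filled += len(good)
        return out

    return propose


def smc_sample(score_theta: Callable[[np.ndarray], float],
               epsilon_final: float, cfg: SMCConfig,
               seed: int | np.random.Generator,
               cell_id: str = "", run_id: int = 1) -> ParameterEnsemble:
    """Run the sequential ABC loop against an arbitrary score closure.

    ``score_theta`` closes over the cell's processed data and the
    simulation protocol; ``epsilon_final`` is the cell's noise floor
    (see :func:`castates.preprocess.noise_floor`).

    Iteration 0 samples the box prior under the preliminary threshold;
    each later iteration proposes from the perturbed previous population
    with the threshold at the configured quantile of the previous
    scores (never below ``epsilon_final``).  Success requires every
    particle at or below ``epsilon_final``; hitting ``max_iterations``
    or an unreachable threshold yields a non-fitted ensemble.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    propose = _prior_proposer(cfg.prior_halfwidth)
    epsilon = cfg.epsilon_prelim
    thresholds: list[float] = []
    total = 0
    pop = np.empty((0, N_PARAMS))
    scores_arr = np.empty(0)
    iterations = 0

    for iteration in range(cfg.max_iterations):
        try:
            pop, scores_arr, used = rejection_sample(
                propose, score_theta, epsilon, cfg.n_particles, rng,
                acceptance_floor=cfg.acceptance_floor,
                batch=cfg.proposal_batch)
        except ThresholdUnreachable:
            return ParameterEnsemble(
                particles=pop, scores=scores_arr,
                epsilon_final=epsilon_final, cell_id=cell_id, run_id=run_id,
                iterations_used=iterations, fitted=False,
                total_proposals=total, thresholds=thresholds)
        total += used
        iterations = iteration + 1
        thresholds.append(epsilon)
        if np.all(scores_arr <= epsilon_final):
            return ParameterEnsemble(
                particles=pop, scores=scores_arr,
                epsilon_final=epsilon_final, cell_id=cell_id, run_id=run_id,
                iterations_used=iterations, fitted=True,
                total_proposals=total, thresholds=thresholds)
        new_eps = float(np.quantile(scores_arr, cfg.quantile))
        epsilon = max(epsilon_final, min(new_eps, epsilon
                                         if math.isfinite(epsilon)
                                         else new_eps))
        propose = _kernel_proposer(pop, cfg.prior_halfwidth,
                                   cfg.kernel_scale)

    return ParameterEnsemble(
        particles=pop, scores=scores_arr, epsilon_final=epsilon_final,
        cell_id=cell_id, run_id=run_id, iterations_used=iterations,
        fitted=False, total_proposals=total, thresholds=thresholds)


def make_cell_scorer(data: "CalciumTrace", atp: float = 10.0,
                     score_cfg: ScoreConfig = ScoreConfig()
                     ) -> Callable[[np.ndarray], float]:
    """Simulate-and-score closure for one processed post-stimulus trace.

    The simulation grid is taken from the data (stimulus at t=0, basal
    calcium anchored to the first data point); failed simulations score
    ``inf`` so the SMC loop treats them as rejections.
    """
    from castates.model import (RestStateError, SimulationError,
                                StimulusProtocol, simulate)

    values = data.values
    protocol = StimulusProtocol(atp=atp, t_on=0.0,
                                duration=(len(values) - 1) * data.dt,
                                dt_out=data.dt)
    basal = float(values[0])

    def score_theta(theta: np.ndarray) -> float:
        try:
            sim = simulate(theta, protocol, basal)
        except (SimulationError, RestStateError):
            return math.inf
        return score(sim, values, score_cfg)

    return score_theta


def fit_cell(data: "CalciumTrace", epsilon_final: float, cfg: SMCConfig,
             seed: int | np.random.Generator, atp: float = 10.0,
             score_cfg: ScoreConfig = ScoreConfig(),
             run_id: int = 1) -> ParameterEnsemble:
    """Fit one cell's processed trace with the full ABC-SMC loop.

    Convenience wrapper around :func:`make_cell_scorer` and
    :func:`smc_sample`.
    """
    scorer = make_cell_scorer(data, atp=atp, score_cfg=score_cfg)
    return smc_sample(scorer, epsilon_final, cfg, seed,
                      cell_id=data.cell_id, run_id=run_id)
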