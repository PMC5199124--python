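"""Ground-truth synthetic single-cell calcium populations.

Cells are drawn from a small number of parameter regimes — log10-normal
clouds around offsets from the reference parameters, truncated to the
prior box — and rendered into raw fluorescence-like calcium traces by
simulating the ODE model, prepending a resting baseline, and adding a
band-limited high-frequency nuisance component plus iid measurement
noise.  The defaults encode three regimes that differ chiefly in the
IP3R feedback constants (d1, d5, dinh).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from castates.model import (
    PARAMETER_NAMES,
    RestStateError,
    SimulationError,
    StimulusProtocol,
    simulate,
)
from castates.preprocess import CalciumTrace

__all__ = [
    "RegimeSpec",
    "NoiseSpec",
    "default_regimes",
    "sample_population",
    "render_traces",
]

_IDX = {name: i for i, name in enumerate(PARAMETER_NAMES)}


@dataclass(frozen=True)
class RegimeSpec:
    """One parameter regime of the synthetic population.

    ``offsets`` maps parameter names to log10 mean shifts from the
    reference values; unnamed parameters center at zero.  ``spread`` is
    the within-regime log10 SD (scalar, applied to all parameters).
    """

    name: str
    offsets: dict[str, float] = field(default_factory=dict)
    spread: float = 0.05
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.spread < 0:
            raise ValueError("spread must be >= 0")
        if self.weight < 0:
            raise ValueError("weight must be >= 0")
        unknown = set(self.offsets) - set(PARAMETER_NAMES)
        if unknown:
            raise ValueError(f"unknown parameters in offsets: {sorted(unknown)}")

    def mean_theta(self) -> np.ndarray:
        theta = np.zeros(len(PARAMETER_NAMES))
        for name, off in self.offsets.items():
            theta[_IDX[name]] = off
        return theta


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise model for rendered traces.

    ``sigma_meas`` is the iid additive Gaussian SD (uM); the nuisance
    component is a random band-limited signal of amplitude ``hf_amp``
    centered at ``hf_freq`` Hz, standing in for fast biology the ODE
    model does not capture.
    """

    sigma_meas: float = 0.01
    hf_amp: float = 0.01
    hf_freq: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_meas < 0 or self.hf_amp < 0 or self.hf_freq < 0:
            raise ValueError("noise magnitudes must be nonnegative")


def default_regimes(magnitude: float = 0.5, spread: float = 0.05
                    ) -> list[RegimeSpec]:
    """Three regimes differing in IP3R calcium-feedback constants.

    * strong-positive: strong calcium activation (low d5), weak
      inactivation (high dinh) — large sustained responses;
    * strong-negative: strong calcium inactivation (low dinh) with
      elevated receptor/PLC gain — sharp spike, low plateau;
    * weak-positive: weak calcium and IP3 activation (high d5, high d1,
      slightly faster gating) — small, slow responses.
    """
    m = magnitude
    return [
        RegimeSpec("strong-positive",
                   {"d5": -m, "dinh": +0.8 * m}, spread=spread, weight=0.4),
        RegimeSpec("strong-negative",
                   {"dinh": -m, "k_plc": +0.2}, spread=spread, weight=0.3),
        RegimeSpec("weak-positive",
                   {"d1": +0.8 * m, "d5": +0.5 * m, "a2": +0.25},
                   spread=spread, weight=0.3),
    ]


def sample_population(regimes, n_cells: int,
                      seed: int | np.random.Generator,
                      prior_halfwidth: float = 1.0
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-cell true parameter vectors with regime labels.

    Regime assignment is multinomial by weight; within a regime, theta
    is Gaussian in log10 space around the regime mean, truncated to the
    prior box by redrawing out-of-box components' cells.

    Returns
    -------
    (thetas, labels) : (n_cells, 17) float array and (n_cells,) int array
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    regimes = list(regimes)
    weights = np.array([r.weight for r in regimes], dtype=float)
    if not weights.sum() > 0:
        raise ValueError("regime weights must sum to a positive value")
    weights = weights / weights.sum()
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    labels = rng.choice(len(regimes), size=n_cells, p=weights)
    thetas = np.empty((n_cells, len(PARAMETER_NAMES)))
    for i, lab in enumerate(labels):
        reg = regimes[lab]
        mean = reg.mean_theta()
        for _ in range(1000):
            theta = mean + rng.normal(scale=reg.spread, size=mean.shape)
            if np.all(np.abs(theta) <= prior_halfwidth):
                break
        else:
            raise RuntimeError(
                f"could not draw an in-box theta for regime {reg.name!r}")
        thetas[i] = theta
    return thetas, labels


def _band_limited_noise(n: int, dt: float, center_hz: float, amp: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Random narrowband signal of RMS ``amp`` around ``center_hz``."""
    if amp == 0 or n < 4:
        return np.zeros(n)
    freqs = np.fft.rfftfreq(n, d=dt)
    band = (freqs >= 0.5 * center_hz) & (freqs <= 1.5 * center_hz)
    if not band.any():
        band = freqs >= freqs[len(freqs) // 2]  # fall back to upper half
    spectrum = np.zeros(len(freqs), dtype=complex)
    phases = rng.uniform(0, 2 * np.pi, size=int(band.sum()))
    spectrum[band] = np.exp(1j * phases)
    x = np.fft.irfft(spectrum, n=n)
    rms = np.sqrt(np.mean(x ** 2))
    return amp * x / rms if rms > 0 else x


def render_traces(thetas: np.ndarray, protocol: StimulusProtocol,
                  noise: NoiseSpec, basal_ca: float = 0.05,
                  regimes=None, labels=None,
                  rng: np.random.Generator | None = None,
                  max_resample: int = 50):
    """Render parameter vectors into noisy raw traces.

    Each trace is the ODE simulation on the protocol grid (the
    pre-stimulus baseline is the rest state) plus band-limited nuisance
    and iid Gaussian measurement noise.  A theta whose simulation fails
    is redrawn within its regime when ``regimes``/``labels`` are given,
    otherwise the failure propagates.

    Returns
    -------
    (traces, thetas_used) : list of CalciumTrace, (n, 17) array
    """
    rng = rng if rng is not None else np.random.default_rng(noise.seed)
    thetas = np.asarray(thetas, dtype=float)
    grid = protocol.time_grid()
    stim_index = protocol.stim_index()
    traces: list[CalciumTrace] = []
    used = thetas.copy()
    for i, theta in enumerate(thetas):
        ca = None
        for attempt in range(max_resample):
            try:
                ca = simulate(used[i], protocol, basal_ca)
                break
            except (SimulationError, RestStateError):
                if regimes is None or labels is None:
                    raise
                reg = regimes[labels[i]]
                redraw, _ = sample_population([reg], 1, rng)
                used[i] = redraw[0]
        if ca is None:
            raise SimulationError(
                f"cell {i}: no simulable theta after {max_resample} redraws")
        hf = _band_limited_noise(len(grid), protocol.dt_out,
                                 noise.hf_freq, noise.hf_amp, rng)
        meas = rng.normal(scale=noise.sigma_meas, size=len(grid)) \
            if noise.sigma_meas > 0 else 0.0
        values = ca + hf + meas
        traces.append(CalciumTrace(values=values, dt=protocol.dt_out,
                                   stim_index=stim_index,
                                   cell_id=f"cell{i:04d}"))
    return traces, used
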