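"""Four-variable ODE model of ATP-induced calcium release.

State variables: cytosolic IP3, active PLC, cytosolic free calcium, and
the fraction ``h`` of ER calcium-channel (IP3R) subunits not yet
inactivated by calcium.  Receptor dynamics are collapsed into a ligand
step multiplied by an exponential desensitization factor, so the state
count stays at four.  ER calcium is eliminated through a conserved-total
constraint; a single multiplicative factor accounts for cytosolic
calcium buffering.  Channel gating follows the reduced two-variable
IP3R formulation (activation at equilibrium, inactivation dynamic).

The 17 free kinetic parameters are enumerated in :data:`PARAMETER_NAMES`
and their reference values ship in ``data/reference_parameters.tsv``.
Inference operates on log10 fold-changes from those references.
"""

from __future__ import annotations

import importlib.resources
import math
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.integrate import ODEintWarning, odeint

__all__ = [
    "PARAMETER_NAMES",
    "N_STATE_VARIABLES",
    "ModelState",
    "ReferenceParameters",
    "StimulusProtocol",
    "SimulationError",
    "RestStateError",
    "reference_parameters",
    "params_from_theta",
    "leak_rate",
    "rhs",
    "find_rest_state",
    "simulate",
]

#: Frozen ordering of the 17 free kinetic parameters.  Every
#: :class:`~castates.fitting.ParameterEnsemble` column, every theta
#: vector and every on-disk particle file follows this order.
PARAMETER_NAMES: tuple[str, ...] = (
    "d1",          # IP3R: IP3-activation equilibrium constant (uM)
    "d5",          # IP3R: Ca-activation equilibrium constant (uM)
    "dinh",        # IP3R: Ca-inactivation equilibrium constant (uM)
    "a2",          # IP3R: inactivation gating rate (1/(uM*s))
    "v_rel",       # maximal IP3R channel flux rate (1/s)
    "v_serca",     # SERCA maximal pump rate (uM/s)
    "k_serca",     # SERCA half-saturation (uM)
    "k_plc",       # receptor/PLC activation gain (PLC units/s per uM ATP)
    "k_r",         # receptor desensitization rate (1/s)
    "k_plc_deg",   # PLC deactivation rate (1/s)
    "v_ip3",       # maximal IP3 production rate (uM/s)
    "k_hill",      # PLC half-saturation of IP3 production (PLC units)
    "n_hill",      # Hill coefficient of IP3 production (dimensionless)
    "k_ip3_deg",   # IP3 linear degradation rate (1/s)
    "c1",          # ER:cytosol volume ratio (dimensionless)
    "c0",          # total conserved calcium, cytosolic equivalent (uM)
    "b_buf",       # free fraction of cytosolic calcium (buffer factor)
)

N_STATE_VARIABLES = 4


class SimulationError(RuntimeError):
    """Integration failed or produced an inadmissible trajectory."""


class RestStateError(ValueError):
    """No admissible pre-stimulus rest state for these parameters."""


@dataclass(frozen=True)
class ModelState:
    """One point of the model state space.

    Attributes
    ----------
    ip3 : float
        Cytosolic IP3 concentration (uM).
    plc : float
        Active PLC level (arbitrary concentration units).
    ca : float
        Cytosolic free calcium (uM).
    h : float
        Fraction of IP3R channels not calcium-inactivated.
    """

    ip3: float
    plc: float
    ca: float
    h: float

    def __post_init__(self) -> None:
        vals = (self.ip3, self.plc, self.ca, self.h)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError(f"non-finite model state: {vals}")
        if self.ca < 0:
            raise ValueError(f"negative calcium: {self.ca}")
        if not 0.0 <= self.h <= 1.0:
            raise ValueError(f"h outside [0, 1]: {self.h}")

    def as_array(self) -> np.ndarray:
        return np.array([self.ip3, self.plc, self.ca, self.h], dtype=float)


@dataclass(frozen=True)
class StimulusProtocol:
    """ATP stimulation and simulation grid.

    Attributes
    ----------
    atp : float
        Ligand concentration L (uM) applied from ``t_on`` onward.
    t_on : float
        Stimulus onset time (s).
    duration : float
        Total simulated time (s).
    dt_out : float
        Output sampling interval (s).
    """

    atp: float = 10.0
    t_on: float = 60.0
    duration: float = 660.0
    dt_out: float = 2.0

    def __post_init__(self) -> None:
        if self.atp < 0:
            raise ValueError("atp must be >= 0")
        if self.t_on < 0:
            raise ValueError("t_on must be >= 0")
        if self.duration <= self.t_on:
            raise ValueError("duration must exceed t_on")
        if self.dt_out <= 0:
            raise ValueError("dt_out must be > 0")

    def time_grid(self) -> np.ndarray:
        """Output time grid from 0 to ``duration`` inclusive-of-endpoint."""
        n = int(math.floor(self.duration / self.dt_out)) + 1
        return np.arange(n) * self.dt_out

    def stim_index(self) -> int:
        """Index of the first grid point at or after stimulus onset."""
        return int(math.ceil(self.t_on / self.dt_out - 1e-9))


class ReferenceParameters(dict):
    """Named map of the 17 kinetic constants in natural units.

    A thin dict subclass that validates completeness and positivity on
    construction so a malformed reference table fails loudly.
    """

    def __init__(self, values: Mapping[str, float]):
        missing = set(PARAMETER_NAMES) - set(values)
        extra = set(values) - set(PARAMETER_NAMES)
        if missing or extra:
            raise ValueError(
                f"reference parameter set mismatch: missing={sorted(missing)}, "
                f"unexpected={sorted(extra)}"
            )
        for name in PARAMETER_NAMES:
            v = float(values[name])
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"reference value for {name!r} must be finite "
                                 f"and > 0, got {v}")
        super().__init__({name: float(values[name]) for name in PARAMETER_NAMES})

    def as_array(self) -> np.ndarray:
        return np.array([self[k] for k in PARAMETER_NAMES], dtype=float)


_REFERENCE_CACHE: ReferenceParameters | None = None


def reference_parameters() -> ReferenceParameters:
    """Load the shipped reference parameter table (cached)."""
    global _REFERENCE_CACHE
    if _REFERENCE_CACHE is None:
        text = (
            importlib.resources.files("castates")
            .joinpath("data/reference_parameters.tsv")
            .read_text()
        )
        values: dict[str, float] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("name\t"):
                continue
            fields = line.split("\t")
            values[fields[0]] = float(fields[1])
        _REFERENCE_CACHE = ReferenceParameters(values)
    return _REFERENCE_CACHE


def params_from_theta(theta: np.ndarray,
                      reference: Mapping[str, float] | None = None
                      ) -> dict[str, float]:
    """Natural-scale parameter map from a log10 fold-change vector."""
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (len(PARAMETER_NAMES),):
        raise ValueError(f"theta must have shape ({len(PARAMETER_NAMES)},), "
                         f"got {theta.shape}")
    if not np.all(np.isfinite(theta)):
        raise ValueError("theta contains non-finite entries")
    ref = reference if reference is not None else reference_parameters()
    return {name: ref[name] * 10.0 ** theta[i]
            for i, name in enumerate(PARAMETER_NAMES)}


def _serca_flux(ca: float, v_serca: float, k_serca: float) -> float:
    ca2 = ca * ca
    return v_serca * ca2 / (k_serca * k_serca + ca2)


def leak_rate(params: Mapping[str, float], basal_ca: float) -> float:
    """ER leak coefficient balancing SERCA pumping at the rest state.

    The leak is not a free parameter: it is fixed by requiring zero net
    calcium flux at the pre-stimulus basal level, where the IP3R channel
    is closed (no IP3).
    """
    if basal_ca <= 0:
        raise RestStateError(f"basal_ca must be > 0, got {basal_ca}")
    ca_er = (params["c0"] - basal_ca) / params["c1"]
    gradient = ca_er - basal_ca
    if gradient <= 0:
        raise RestStateError(
            "no admissible rest state: ER calcium gradient non-positive "
            f"(c0={params['c0']}, c1={params['c1']}, basal={basal_ca})"
        )
    return _serca_flux(basal_ca, params["v_serca"], params["k_serca"]) / gradient


def rhs(state: ModelState, t: float, params: Mapping[str, float],
        protocol: StimulusProtocol, v_leak: float = 0.0) -> np.ndarray:
    """Time derivatives (per second) of the four state variables.

    ``v_leak`` is the derived ER leak coefficient (see :func:`leak_rate`);
    it defaults to zero, which corresponds to a leak-free ER membrane.
    """
    f = _make_rhs(params, protocol, v_leak)
    dy = f(t, state.as_array())
    if not np.all(np.isfinite(dy)):
        raise SimulationError(f"non-finite derivative at t={t}: {dy}")
    return dy


def _make_rhs(params: Mapping[str, float], protocol: StimulusProtocol,
              v_leak: float):
    """Closure evaluating the ODE right-hand side on raw state arrays.

    Scalar math throughout: this function dominates the inference
    runtime, and avoiding numpy per-element overhead matters.
    """
    d1 = params["d1"]; d5 = params["d5"]; dinh = params["dinh"]
    a2 = params["a2"]; v_rel = params["v_rel"]
    v_serca = params["v_serca"]; k_serca = params["k_serca"]
    k_plc = params["k_plc"]; k_r = params["k_r"]; k_plc_deg = params["k_plc_deg"]
    v_ip3 = params["v_ip3"]; k_hill = params["k_hill"]; n_hill = params["n_hill"]
    k_ip3_deg = params["k_ip3_deg"]
    c1 = params["c1"]; c0 = params["c0"]; b_buf = params["b_buf"]
    atp = protocol.atp; t_on = protocol.t_on
    k_serca2 = k_serca * k_serca
    k_hill_n = k_hill ** n_hill

    def f(t: float, y) -> np.ndarray:
        ip3, plc, ca, h = y[0], y[1], y[2], y[3]

        # ligand step with first-order receptor desensitization
        ligand = atp * math.exp(-k_r * (t - t_on)) if t >= t_on else 0.0
        dplc = k_plc * ligand - k_plc_deg * plc

        if plc > 0.0:
            plc_n = plc ** n_hill
            production = v_ip3 * plc_n / (k_hill_n + plc_n)
        else:
            production = 0.0
        dip3 = production - k_ip3_deg * ip3

        ca_er = (c0 - ca) / c1
        if ip3 > 0.0 and ca > 0.0:
            m_inf = ip3 / (ip3 + d1)
            n_inf = ca / (ca + d5)
            p_open = (m_inf * n_inf * h) ** 3
        else:
            p_open = 0.0
        ca2 = ca * ca
        j_serca = v_serca * ca2 / (k_serca2 + ca2)
        dca = b_buf * ((v_rel * p_open + v_leak) * (ca_er - ca) - j_serca)

        dh = a2 * (dinh * (1.0 - h) - ca * h)
        return np.array([dip3, dplc, dca, dh])

    return f


def _make_flat_rhs():
    """Flat-parameter RHS for the integrator hot path, numba-jit when
    available.

    Must stay algebraically identical to :func:`_make_rhs`; the test
    suite cross-checks the two (and an SBML re-integration) against each
    other.
    """
    def rhs_flat(t, y, pv):
        d1 = pv[0]; d5 = pv[1]; dinh = pv[2]; a2 = pv[3]
        v_rel = pv[4]; v_serca = pv[5]; k_serca = pv[6]
        k_plc = pv[7]; k_r = pv[8]; k_plc_deg = pv[9]
        v_ip3 = pv[10]; k_hill = pv[11]; n_hill = pv[12]
        k_ip3_deg = pv[13]; c1 = pv[14]; c0 = pv[15]; b_buf = pv[16]
        atp = pv[17]; t_on = pv[18]; v_leak = pv[19]
        ip3, plc, ca, h = y[0], y[1], y[2], y[3]
        ligand = atp * math.exp(-k_r * (t - t_on)) if t >= t_on else 0.0
        dplc = k_plc * ligand - k_plc_deg * plc
        if plc > 0.0:
            plc_n = plc ** n_hill
            production = v_ip3 * plc_n / (k_hill ** n_hill + plc_n)
        else:
            production = 0.0
        dip3 = production - k_ip3_deg * ip3
        ca_er = (c0 - ca) / c1
        if ip3 > 0.0 and ca > 0.0:
            p_open = (ip3 / (ip3 + d1) * ca / (ca + d5) * h) ** 3
        else:
            p_open = 0.0
        ca2 = ca * ca
        j_serca = v_serca * ca2 / (k_serca * k_serca + ca2)
        dca = b_buf * ((v_rel * p_open + v_leak) * (ca_er - ca) - j_serca)
        dh = a2 * (dinh * (1.0 - h) - ca * h)
        out = np.empty(4)
        out[0] = dip3; out[1] = dplc; out[2] = dca; out[3] = dh
        return out

    try:
        import numba
        return numba.njit(rhs_flat)
    except ImportError:  # pragma: no cover - numba is an optional speedup
        return rhs_flat


_RHS_FLAT = _make_flat_rhs()


def find_rest_state(params: Mapping[str, float], basal_ca: float) -> ModelState:
    """Pre-stimulus rest state with resting calcium equal to ``basal_ca``.

    With no ligand the IP3/PLC subsystem rests at zero, the channel is
    closed, the gating variable sits at its equilibrium and the derived
    leak (see :func:`leak_rate`) balances SERCA, so the rest state is
    exact in closed form.
    """
    leak_rate(params, basal_ca)  # validates admissibility
    h_rest = params["dinh"] / (params["dinh"] + basal_ca)
    return ModelState(ip3=0.0, plc=0.0, ca=float(basal_ca), h=h_rest)


def simulate(theta: np.ndarray, protocol: StimulusProtocol, basal_ca: float,
             reference: Mapping[str, float] | None = None,
             rtol: float = 1e-6, atol: float = 1e-9) -> np.ndarray:
    """Integrate the model and sample calcium on the protocol's grid.

    Parameters
    ----------
    theta : array of shape (17,)
        log10 fold-changes from the reference parameters.
    protocol : StimulusProtocol
    basal_ca : float
        Resting cytosolic calcium (uM); anchors the initial condition.

    Returns
    -------
    numpy.ndarray
        Calcium concentration (uM) on ``protocol.time_grid()``.

    Raises
    ------
    SimulationError
        On solver failure or an inadmissible trajectory (non-finite
        values, negative implied ER calcium).  SMC callers catch this
        and score the particle as a rejection.
    RestStateError
        If no admissible rest state exists for these parameters.
    """
    params = params_from_theta(theta, reference)
    rest = find_rest_state(params, basal_ca)
    v_leak = leak_rate(params, basal_ca)
    grid = protocol.time_grid()

    # the pre-stimulus segment is exactly the rest state
    pre_mask = grid < protocol.t_on
    ca_out = np.full(grid.shape, basal_ca, dtype=float)
    post_grid = grid[~pre_mask]
    if post_grid.size == 0:
        return ca_out

    pv = np.empty(20)
    for i, name in enumerate(PARAMETER_NAMES):
        pv[i] = params[name]
    pv[17] = protocol.atp
    pv[18] = protocol.t_on
    pv[19] = v_leak

    # LSODA (stiff-capable) via odeint: much lower per-call overhead
    # than solve_ivp for this 4-variable system
    t_ode = post_grid
    prepend = t_ode[0] > protocol.t_on
    if prepend:
        t_ode = np.concatenate([[protocol.t_on], t_ode])
    with warnings.catch_warnings():
        warnings.simplefilter("error", ODEintWarning)
        try:
            y, info = odeint(_RHS_FLAT, rest.as_array(), t_ode,
                             args=(pv,), rtol=rtol, atol=atol,
                             tfirst=True, full_output=True,
                             printmessg=False)
        except (ODEintWarning, OverflowError, FloatingPointError,
                ValueError) as exc:
            raise SimulationError(f"integration failed: {exc}") from exc
    if info["message"] != "Integration successful.":
        raise SimulationError(f"integration failed: {info['message']}")
    if prepend:
        y = y[1:]
    ca = y[:, 2]
    if not np.all(np.isfinite(y)):
        raise SimulationError("non-finite state in trajectory")
    if np.any(ca < -atol) or np.any(ca > params["c0"] * (1 + 1e-9)):
        raise SimulationError("trajectory leaves admissible calcium range "
                              "(implied ER calcium negative or Ca < 0)")
    ca_out[~pre_mask] = np.clip(ca, 0.0, None)
    return ca_out
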