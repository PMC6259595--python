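"""Excitable-membrane models built from general-current terms.

Each transmembrane mechanism contributes a capacitance-normalised
current ``J_l = a_l * p_l * phi_l(v)`` (pA/pF = mV/ms), where ``a_l`` is
an amplitude, ``p_l`` a gating occupancy and

    phi_l(v) = exp[b_l x_l] - exp[(b_l - 1) x_l],
    x_l = (eta_l v - vo_l) / v_T

is the two-exponential kernel of the thermodynamic current with the
mechanism's net charge count ``eta_l`` and reversal parameter ``vo_l``.
The membrane potential then obeys ``dv/dt = -sum_l J_l (+ stimulus)``.

Two fully parameterised models are provided:

* :class:`SANModel` — a three-variable (v, w, c) cardiac sinoatrial-node
  pacemaker driven by L-type Ca2+ channels, delayed-rectifier K+
  channels, Na-K ATPases and Na-Ca exchangers, with intracellular Ca2+
  feeding back on the Ca2+ Nernst potential.  It oscillates
  spontaneously with a period near 375 ms.
* :class:`FSModel` — a two-variable (v, w) striatal fast-spiking
  interneuron with transient Na+ channels, delayed-rectifier K+
  channels and a Na-K pump, silent at rest and firing repetitively
  above a rheobase current step of 40-50 pA.

Sign conventions.  Channel amplitudes printed as positive magnitudes
carry the sign of their charge count: the Ca2+ and Na+ channel currents
(eta < 0) enter the voltage equation with a negative sign, making them
inward (depolarising), while K+ channel and Na-K pump currents
(eta > 0) are outward above reversal.  The exchanger current keeps its
positive printed amplitude with the (eta = -1) kernel; the Ca2+ balance
counts both the L-type and the exchanger current with the sign that
makes inward Ca2+ movement raise ``c``.  This is the one configuration
of the model that pacemakes; see docs/methods.md for the full analysis.

Time is in ms throughout; gating rates printed in the source tables as
"s^-1" are interpreted on the ms scale (see ``literal_rate_units``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .constants import Constants, DEFAULT_CONSTANTS

__all__ = [
    "phi",
    "gating_steady_state",
    "gating_rate",
    "GatingParams",
    "SANParams",
    "FSParams",
    "StateSAN",
    "Trajectory",
    "san_derivatives",
    "fs_derivatives",
    "integrate",
    "SANModel",
    "FSModel",
]


def phi(x, b: float):
    """Two-exponential current kernel ``exp(b x) - exp((b-1) x)``.

    ``x`` is the (dimensionless) energy drop ``(eta v - v_o)/v_T``.
    Vanishes at x = 0; reduces to ``2 sinh(x/2)`` at b = 1/2.
    """
    if not 0.0 <= b <= 1.0:
        raise ValueError("bias must lie in [0, 1]")
    x = np.asarray(x, dtype=float)
    out = np.exp(b * x) - np.exp((b - 1.0) * x)
    return out.item() if out.ndim == 0 else out


def gating_steady_state(v, g_u: float, v_u: float,
                        constants: Constants = DEFAULT_CONSTANTS):
    """Sigmoidal steady-state activation ``F_u(v)``.

    Logistic in ``g_u (v - v_u)/v_T``: one half at the half-activation
    potential ``v_u``, increasing in v with steepness ``g_u``.
    """
    x = g_u * (np.asarray(v, dtype=float) - v_u) / constants.v_T
    out = 1.0 / (1.0 + np.exp(-x))
    return out.item() if out.ndim == 0 else out


@dataclass(frozen=True)
class GatingParams:
    """Voltage-dependent gate: steady state and activation rate.

    ``g_u`` and ``v_u`` shape the steady state; ``r_w`` (ms^-1), ``b_w``
    and ``k_w`` shape the kinetics of the activation variable.
    """

    g_u: float
    v_u: float
    r_w: float
    b_w: float = 0.5
    k_w: float = 1.0

    def __post_init__(self) -> None:
        if self.r_w <= 0:
            raise ValueError("gating rate r_w must be positive")
        if self.k_w <= 0:
            raise ValueError("gating exponent k_w must be positive")
        if not 0.0 <= self.b_w <= 1.0:
            raise ValueError("gating bias b_w must lie in [0, 1]")


def gating_rate(v, gp: GatingParams, constants: Constants = DEFAULT_CONSTANTS):
    """Voltage-dependent activation rate ``R_w(v)`` in ms^-1.

    ``r_w [exp(b_w y) + exp((b_w - 1) y)]`` with
    ``y = g_w (v - v_w)/v_T``; equals ``2 r_w`` at ``v = v_w`` and is a
    hyperbolic cosine (symmetric about v_w) when ``b_w = 1/2``.
    """
    y = gp.g_u * (np.asarray(v, dtype=float) - gp.v_u) / constants.v_T
    out = gp.r_w * (np.exp(gp.b_w * y) + np.exp((gp.b_w - 1.0) * y))
    return out.item() if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Parameter sets


@dataclass(frozen=True)
class SANParams:
    """Cardiac sinoatrial-node pacemaker parameters.

    Defaults are the published working set: amplitudes ``a_x`` are
    capacitance-normalised (pA/pF) from whole-cell amplitudes of 1, 100,
    1 and 3 pA over 30 pF.  ``v_nak`` composes to
    ``3 v_na - 2 v_k + v_atp = -62 mV``.

    ``ca_out_uM`` (extracellular Ca2+, absent from the published table)
    defaults to 2 mM; the Ca2+ Nernst potential is computed from it and
    the dynamic intracellular concentration ``c``.

    ``literal_rate_units`` re-reads the gating rate as a literal
    ``s^-1`` value (dividing by 1000).  The default interprets it on the
    ms scale of the voltage equation, without which the model is three
    orders of magnitude away from the published periods.
    """

    c_m_pF: float = 30.0
    a_ca: float = 1.0 / 30.0      # pA/pF, L-type Ca2+
    a_k: float = 100.0 / 30.0     # pA/pF, delayed-rectifier K+
    a_nak: float = 1.0 / 30.0     # pA/pF, Na-K ATPase
    a_naca: float = 3.0 / 30.0    # pA/pF, Na-Ca exchanger
    v_atp: float = -420.0         # mV
    v_na: float = 60.0            # mV
    v_k: float = -89.0            # mV
    v_m13: float = -25.0          # mV, L-type half-activation
    g_m13: float = 5.0            # L-type activation steepness
    v_w: float = -25.0            # mV, K+ half-activation
    g_w: float = 3.6              # K+ activation steepness
    r_w: float = 0.005            # ms^-1, K+ activation rate
    k_w: float = 0.3              # K+ activation exponent
    b_w: float = 0.35             # K+ activation bias
    b_nak: float = 0.35           # pump rectification bias
    b_k: float = 0.1              # K+ current rectification bias
    b_naca: float = 0.5           # exchanger bias (unrectified)
    b_ca: float = 0.5             # L-type bias (unrectified)
    c_inf_uM: float = 0.1         # resting intracellular Ca2+
    r_c: float = 0.02             # ms^-1, Ca2+ removal rate
    k_c: float = 0.00554          # uM per (pA/pF * ms), flux-to-concentration
    ca_out_uM: float = 2000.0     # extracellular Ca2+
    literal_rate_units: bool = False

    @property
    def v_nak(self) -> float:
        """Na-K ATPase reversal: 3 v_Na - 2 v_K + v_ATP (mV)."""
        return 3.0 * self.v_na - 2.0 * self.v_k + self.v_atp

    @property
    def r_w_eff(self) -> float:
        return self.r_w / 1000.0 if self.literal_rate_units else self.r_w

    @property
    def w_gate(self) -> GatingParams:
        return GatingParams(g_u=self.g_w, v_u=self.v_w, r_w=self.r_w_eff,
                            b_w=self.b_w, k_w=self.k_w)

    def v_ca(self, c_uM, constants: Constants = DEFAULT_CONSTANTS):
        """Ca2+ Nernst potential at intracellular concentration c (uM)."""
        return 0.5 * constants.v_T * np.log(self.ca_out_uM / np.asarray(c_uM, dtype=float))


@dataclass(frozen=True)
class FSParams:
    """Striatal fast-spiking interneuron parameters.

    Whole-cell amplitudes (67, 4400, 1400 pA) over 30 pF;
    ``v_nak = 3 v_na - 2 v_k + v_atp = -72 mV``.  All channel biases are
    1/2 (unrectified); gating kinetics follow the same logistic scheme
    as the pacemaker but with a linear (k_w = 1) activation exponent.
    """

    c_m_pF: float = 30.0
    abar_nak: float = 67.0        # pA, Na-K ATPase
    abar_k: float = 4400.0        # pA, delayed-rectifier K+
    abar_na: float = 1400.0       # pA, transient Na+
    v_atp: float = -430.0         # mV
    v_k: float = -89.0            # mV
    v_na: float = 60.0            # mV
    v_mt: float = -17.0           # mV, Na+ half-activation
    g_mt: float = 5.0             # Na+ activation steepness
    v_w: float = -5.0             # mV, K+ half-activation
    g_w: float = 4.0              # K+ activation steepness
    r_w: float = 2.0              # ms^-1, K+ activation rate
    k_w: float = 1.0              # K+ activation exponent
    b_w: float = 0.3              # K+ activation bias
    b_nak: float = 0.5
    b_k: float = 0.5
    b_na: float = 0.5
    stim_amplitude_pA: float = 0.0
    literal_rate_units: bool = False

    @property
    def v_nak(self) -> float:
        return 3.0 * self.v_na - 2.0 * self.v_k + self.v_atp

    @property
    def a_nak(self) -> float:
        return self.abar_nak / self.c_m_pF

    @property
    def a_k(self) -> float:
        return self.abar_k / self.c_m_pF

    @property
    def a_na(self) -> float:
        return self.abar_na / self.c_m_pF

    @property
    def r_w_eff(self) -> float:
        return self.r_w / 1000.0 if self.literal_rate_units else self.r_w

    @property
    def w_gate(self) -> GatingParams:
        return GatingParams(g_u=self.g_w, v_u=self.v_w, r_w=self.r_w_eff,
                            b_w=self.b_w, k_w=self.k_w)


@dataclass(frozen=True)
class StateSAN:
    """Pacemaker state: potential (mV), K+ activation, Ca2+ (uM)."""

    v: float
    w: float
    c: float

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("intracellular Ca2+ must be positive")
        object.__setattr__(self, "w", min(max(self.w, 0.0), 1.0))


# ---------------------------------------------------------------------------
# Derivative functions


def _san_currents(v, w, c, p: SANParams, constants: Constants) -> dict:
    """Capacitance-normalised currents (pA/pF) at a pacemaker state."""
    v_T = constants.v_T
    v_ca = p.v_ca(c, constants)
    j_nak = p.a_nak * phi((v - p.v_nak) / v_T, p.b_nak)
    j_naca = p.a_naca * phi((-v - (2.0 * v_ca - 3.0 * p.v_na)) / v_T, p.b_naca)
    j_kd = p.a_k * w * phi((v - p.v_k) / v_T, p.b_k)
    f_m = gating_steady_state(v, p.g_m13, p.v_m13, constants)
    j_cal = -p.a_ca * (1.0 - w) * f_m * phi((-2.0 * v + 2.0 * v_ca) / v_T, p.b_ca)
    return {"J_NaK": j_nak, "J_NaCa": j_naca, "J_KD": j_kd, "J_CaL": j_cal}


def san_derivatives(state, params: SANParams,
                    constants: Constants = DEFAULT_CONSTANTS) -> np.ndarray:
    """Right-hand side of the pacemaker system, d(v, w, c)/dt.

    ``dv = -(J_NaK + J_NaCa + J_KD + J_CaL)`` (mV/ms),
    ``dw = w^k_w (F_w - w) R_w`` and
    ``dc = r_c (c_inf - c) - k_c (J_CaL + J_NaCa)`` so that inward Ca2+
    movement through either pathway raises the concentration.

    Raises
    ------
    ValueError
        If the Ca2+ concentration is not positive.
    """
    v, w, c = (state.v, state.w, state.c) if isinstance(state, StateSAN) else state
    if c <= 0:
        raise ValueError("intracellular Ca2+ must be positive")
    cur = _san_currents(v, w, c, params, constants)
    dv = -(cur["J_NaK"] + cur["J_NaCa"] + cur["J_KD"] + cur["J_CaL"])
    f_w = gating_steady_state(v, params.g_w, params.v_w, constants)
    dw = max(w, 0.0) ** params.k_w * (f_w - w) * gating_rate(v, params.w_gate, constants)
    dc = params.r_c * (params.c_inf_uM - c) - params.k_c * (cur["J_CaL"] + cur["J_NaCa"])
    return np.array([dv, dw, dc])


def _fs_currents(v, w, p: FSParams, constants: Constants) -> dict:
    v_T = constants.v_T
    f_m = gating_steady_state(v, p.g_mt, p.v_mt, constants)
    j_nat = -p.a_na * (1.0 - w) * f_m * phi((-v + p.v_na) / v_T, p.b_na)
    j_k = p.a_k * w * phi((v - p.v_k) / v_T, p.b_k)
    j_nak = p.a_nak * phi((v - p.v_nak) / v_T, p.b_nak)
    return {"J_NaT": j_nat, "J_K": j_k, "J_NaK": j_nak}


def fs_derivatives(state, params: FSParams, i_stim: float = 0.0,
                   constants: Constants = DEFAULT_CONSTANTS) -> np.ndarray:
    """Right-hand side of the interneuron system, d(v, w)/dt.

    ``dv = -(J_NaT + J_K + J_NaK) + i_stim / C_m`` with the stimulus in
    pA, and the same logistic gating flow as the pacemaker.
    """
    v, w = state
    cur = _fs_currents(v, w, params, constants)
    dv = -(cur["J_NaT"] + cur["J_K"] + cur["J_NaK"]) + i_stim / params.c_m_pF
    f_w = gating_steady_state(v, params.g_w, params.v_w, constants)
    dw = max(w, 0.0) ** params.k_w * (f_w - w) * gating_rate(v, params.w_gate, constants)
    return np.array([dv, dw])


# ---------------------------------------------------------------------------
# Integration


@dataclass
class Trajectory:
    """Time-ordered state samples with per-mechanism current traces.

    ``states`` maps state names (``v``, ``w``, ``c``) and ``currents``
    maps mechanism labels (``J_CaL``...) to arrays aligned with
    ``times`` (ms).  When produced by an in-process simulation the dense
    solver interpolant is retained for sub-sample analyses (upstroke
    velocity); a trajectory read back from disk has ``dense = None``.
    """

    times: np.ndarray
    states: dict
    currents: dict
    meta: dict = field(default_factory=dict)
    dense: Callable | None = None

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        for k, arr in {**self.states, **self.currents}.items():
            if len(arr) != len(self.times):
                raise ValueError(f"trace {k!r} not aligned with times")

    @property
    def v(self) -> np.ndarray:
        return self.states["v"]

    def resample_v(self, dt: float, t_lo: float | None = None,
                   t_hi: float | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Membrane potential on a finer grid (dense interpolant if kept)."""
        t_lo = self.times[0] if t_lo is None else t_lo
        t_hi = self.times[-1] if t_hi is None else t_hi
        tt = np.arange(t_lo, t_hi, dt)
        if self.dense is not None:
            return tt, self.dense(tt)[0]
        return tt, np.interp(tt, self.times, self.v)


def integrate(
    derivatives: Callable,
    init: Sequence[float],
    t_span: tuple[float, float],
    sample_dt: float = 1.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    max_step: float = 0.1,
    method: str = "LSODA",
):
    """Adaptive ODE solve with dense output and fixed-step sampling.

    Thin wrapper over :func:`scipy.integrate.solve_ivp` with stiff-aware
    defaults (the exponential currents are stiff near spikes):
    ``rtol = 1e-8``, ``atol = 1e-10``, ``max_step = 0.1 ms``.
    Deterministic for fixed inputs.

    Raises
    ------
    RuntimeError
        If the solver fails, reporting the last good time.
    """
    t0, t1 = t_span
    if t1 <= t0:
        raise ValueError("t_span must be increasing")
    t_eval = np.arange(t0, t1, sample_dt)
    sol = solve_ivp(
        derivatives, (t0, t1), np.asarray(init, dtype=float),
        method=method, rtol=rtol, atol=atol, max_step=max_step,
        t_eval=t_eval, dense_output=True,
    )
    if not sol.success:
        raise RuntimeError(
            f"integration failed at t = {sol.t[-1] if sol.t.size else t0:.3f} ms: "
            f"{sol.message}"
        )
    return sol


class _MembraneModel:
    """Shared simulate/currents machinery for the two concrete models."""

    state_names: tuple[str, ...]

    def __init__(self, params, constants: Constants = DEFAULT_CONSTANTS):
        self.params = params
        self.constants = constants

    def replace(self, **updates):
        """A copy of the model with updated parameters."""
        return type(self)(replace(self.params, **updates), self.constants)


class SANModel(_MembraneModel):
    """Sinoatrial-node pacemaker model (states v, w, c).

    >>> model = SANModel()
    >>> traj = model.simulate(t_max=7000.0)

    The default initial condition (v = -60 mV, w at its steady state,
    c at its resting value) is on the basin of the pacemaking limit
    cycle; the first ~2000 ms are transient and are discarded by the
    analysis helpers.
    """

    state_names = ("v", "w", "c")

    def __init__(self, params: SANParams | None = None,
                 constants: Constants = DEFAULT_CONSTANTS):
        super().__init__(params or SANParams(), constants)

    def default_init(self, v0: float = -60.0) -> StateSAN:
        w0 = gating_steady_state(v0, self.params.g_w, self.params.v_w, self.constants)
        return StateSAN(v=v0, w=w0, c=self.params.c_inf_uM)

    def currents(self, v, w, c) -> dict:
        """Per-mechanism normalised currents (pA/pF) at a state."""
        return _san_currents(v, w, c, self.params, self.constants)

    def derivatives(self, state) -> np.ndarray:
        return san_derivatives(state, self.params, self.constants)

    def _rhs(self, t, y):
        v, w, c = y
        c = max(c, 1e-9)  # guard the log in v_Ca against solver excursions
        return san_derivatives((v, w, c), self.params, self.constants)

    def simulate(self, t_max: float = 7000.0, init: StateSAN | None = None,
                 sample_dt: float = 0.5, **solver_kw) -> Trajectory:
        init = init or self.default_init()
        sol = integrate(self._rhs, (init.v, init.w, init.c), (0.0, t_max),
                        sample_dt=sample_dt, **solver_kw)
        v, w, c = sol.y
        cur = self.currents(v, w, np.maximum(c, 1e-9))
        states = {"v": v, "w": w, "c": c}
        return Trajectory(times=sol.t, states=states, currents=cur,
                          meta={"model": "san", "t_max": t_max}, dense=sol.sol)


class FSModel(_MembraneModel):
    """Fast-spiking interneuron model (states v, w) under current clamp.

    >>> model = FSModel()
    >>> traj = model.simulate(stim_amplitude=80.0)

    The stimulus is a current step of the given amplitude (pA) switched
    on at ``stim_onset`` ms (after a settling window at rest) and held
    to the end of the simulation.
    """

    state_names = ("v", "w")

    def __init__(self, params: FSParams | None = None,
                 constants: Constants = DEFAULT_CONSTANTS):
        super().__init__(params or FSParams(), constants)

    def default_init(self, v0: float = -72.0) -> tuple[float, float]:
        w0 = gating_steady_state(v0, self.params.g_w, self.params.v_w, self.constants)
        return (v0, w0)

    def currents(self, v, w) -> dict:
        return _fs_currents(v, w, self.params, self.constants)

    def derivatives(self, state, i_stim: float = 0.0) -> np.ndarray:
        return fs_derivatives(state, self.params, i_stim, self.constants)

    def simulate(self, stim_amplitude: float = 0.0, stim_onset: float = 500.0,
                 t_max: float = 2500.0, init=None, sample_dt: float = 0.05,
                 **solver_kw) -> Trajectory:
        init = init if init is not None else self.default_init()

        def rhs(t, y):
            stim = stim_amplitude if t >= stim_onset else 0.0
            return fs_derivatives(y, self.params, stim, self.constants)

        sol = integrate(rhs, init, (0.0, t_max), sample_dt=sample_dt, **solver_kw)
        v, w = sol.y
        cur = self.currents(v, w)
        return Trajectory(
            times=sol.t, states={"v": v, "w": w}, currents=cur,
            meta={"model": "fs", "stim_amplitude": stim_amplitude,
                  "stim_onset": stim_onset, "t_max": t_max},
            dense=sol.sol,
        )
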