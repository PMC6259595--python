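"""The approximation ladder for the general transmembrane current.

The general current of an electrogenic mechanism,
``i(v) = q eta r [exp(b x) - exp((b-1) x)]`` with
``x = (eta v - v_o)/v_T``, admits a family of classical approximations:

* a Taylor expansion around the reversal potential (order 1-3), whose
  linear term is exactly the conductance-based (ohmic) current with
  ``g = eta^2 q r / v_T``;
* the Goldman-Hodgkin-Katz (constant-field) current, which is the
  general current with a voltage-dependent amplitude;
* the hyperbolic-sine form at ``b = 1/2`` (no rectification);
* the saturating rectifier limits at ``b = 0`` and ``b = 1``.

All currents are densities in pA/um^2, conductances in nS/um^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import Constants, DEFAULT_CONSTANTS, Q_PA_MS
from .transport import TransportMechanism, eta, reversal_vo

__all__ = [
    "TaylorExpansion",
    "ConductanceApprox",
    "GHKParams",
    "taylor_coefficients",
    "taylor_expansion",
    "taylor_current",
    "conductance_approx",
    "ghk_current",
    "ghk_amplitude",
    "ghk_via_amplitude",
    "sinh_current",
    "rectifier_limit_current",
    "nak_concentration_form",
]


def _eta_vo(mechanism: TransportMechanism, constants: Constants) -> tuple[int, float]:
    n = eta(mechanism)
    if n == 0:
        raise ValueError(f"{mechanism.name} is non-electrogenic (eta = 0)")
    return n, reversal_vo(mechanism, constants)


@dataclass(frozen=True)
class TaylorExpansion:
    """Polynomial expansion of the current around the reversal potential.

    ``coefficients[k-1]`` multiplies ``((eta v - v_o)/v_T)**k``; the
    common prefactor ``q eta r`` is stored separately.
    """

    center: float              # reversal potential v_o/eta, mV
    prefactor: float           # q * eta * r, pA/um^2
    coefficients: tuple[float, ...]

    @property
    def order(self) -> int:
        return len(self.coefficients)


def taylor_coefficients(b: float, order: int = 3) -> tuple[float, ...]:
    """Expansion coefficients of ``exp(b x) - exp((b-1) x)`` about x = 0.

    The first three are ``1``, ``b - 1/2`` and ``(3 b^2 - 3 b + 1)/6``;
    the quadratic and higher terms carry the rectification bias, which is
    why a purely linear (conductance) model cannot rectify.
    """
    if order not in (1, 2, 3):
        raise ValueError("expansion order must be 1, 2 or 3")
    coeffs = (1.0, b - 0.5, (3.0 * b * b - 3.0 * b + 1.0) / 6.0)
    return coeffs[:order]


def taylor_expansion(
    mechanism: TransportMechanism,
    order: int = 3,
    constants: Constants = DEFAULT_CONSTANTS,
) -> TaylorExpansion:
    n, vo = _eta_vo(mechanism, constants)
    return TaylorExpansion(
        center=vo / n,
        prefactor=Q_PA_MS * n * mechanism.rate,
        coefficients=taylor_coefficients(mechanism.bias, order),
    )


def taylor_current(
    mechanism: TransportMechanism,
    v,
    order: int = 3,
    constants: Constants = DEFAULT_CONSTANTS,
):
    """Taylor-approximate current at order 1, 2 or 3, pA/um^2."""
    exp = taylor_expansion(mechanism, order, constants)
    n, vo = _eta_vo(mechanism, constants)
    x = (n * np.asarray(v, dtype=float) - vo) / constants.v_T
    acc = np.zeros_like(x)
    for k, c in enumerate(exp.coefficients, start=1):
        acc += c * x**k
    out = exp.prefactor * acc
    return out.item() if np.isscalar(v) else out


@dataclass(frozen=True)
class ConductanceApprox:
    """Ohmic (conductance-based) approximation ``i = g (v - reversal)``."""

    g: float          # nS/um^2
    reversal: float   # mV

    def __call__(self, v):
        return self.g * (np.asarray(v, dtype=float) - self.reversal)


def conductance_approx(
    mechanism: TransportMechanism, constants: Constants = DEFAULT_CONSTANTS
) -> ConductanceApprox:
    """Linearise the general current at its reversal potential.

    ``g = eta^2 q r / v_T`` is the exact slope of the general current at
    ``v = v_o/eta`` (for any bias), so the ohmic model is the tangent
    line there; it scales with the square of the moved charge.
    """
    n, vo = _eta_vo(mechanism, constants)
    g = n * n * Q_PA_MS * mechanism.rate / constants.v_T
    return ConductanceApprox(g=g, reversal=vo / n)


@dataclass(frozen=True)
class GHKParams:
    """Constant-field current parameters for one ion type."""

    g_x: float    # amplitude (conductance-like), nS/um^2
    z_x: int      # valence
    x_out: float  # extracellular concentration
    x_in: float   # intracellular concentration

    def __post_init__(self) -> None:
        if self.x_out <= 0 or self.x_in <= 0:
            raise ValueError("concentrations must be strictly positive")
        if self.z_x == 0:
            raise ValueError("GHK current requires a charged species")


def ghk_current(params: GHKParams, v, constants: Constants = DEFAULT_CONSTANTS):
    """Goldman-Hodgkin-Katz (constant-field) current, pA/um^2.

    ``g v [x_out - x_in exp(z v/v_T)] / [1 - exp(z v/v_T)]``.  The v = 0
    singularity is removable; it is evaluated through ``expm1`` (which is
    exact for small arguments) with the analytic limit
    ``-g v_T (x_out - x_in)/z`` substituted at v = 0 itself.
    """
    varr = np.asarray(v, dtype=float)
    u = params.z_x * varr / constants.v_T
    with np.errstate(divide="ignore", invalid="ignore"):
        out = params.g_x * varr * (params.x_out - params.x_in * np.exp(u)) / (-np.expm1(u))
    limit = -params.g_x * constants.v_T * (params.x_out - params.x_in) / params.z_x
    out = np.where(varr == 0.0, limit, out)
    return out.item() if np.isscalar(v) else out


def ghk_amplitude(
    params: GHKParams,
    v,
    b: float,
    constants: Constants = DEFAULT_CONSTANTS,
):
    """Voltage-dependent amplitude ``A_x`` of the two-exponential GHK form.

    ``A_x = g v x_in^(1-b) x_out^b / [exp(b u) - exp((b-1) u)]`` with
    ``u = z v / v_T``.  Although it depends on v, it varies slowly and is
    often frozen at a reference voltage, which turns the GHK current into
    the constant-amplitude general form.
    """
    varr = np.asarray(v, dtype=float)
    u = params.z_x * varr / constants.v_T
    num = params.g_x * varr * params.x_in ** (1.0 - b) * params.x_out**b
    den = np.exp(b * u) - np.exp((b - 1.0) * u)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = num / den
    # both num and den vanish linearly at v = 0
    limit = params.g_x * constants.v_T * params.x_in ** (1.0 - b) * params.x_out**b / params.z_x
    out = np.where(varr == 0.0, limit, out)
    return out.item() if np.isscalar(v) else out


def ghk_via_amplitude(
    params: GHKParams,
    v,
    b: float,
    constants: Constants = DEFAULT_CONSTANTS,
    freeze_at: float | None = None,
):
    """GHK current written as amplitude times the two-exponential kernel.

    ``A_x(v) [exp(b z (v - v_x)/v_T) - exp((b-1) z (v - v_x)/v_T)]`` with
    ``v_x`` the Nernst potential of the ion.  With the exact,
    voltage-dependent amplitude this is algebraically identical to
    :func:`ghk_current` for every bias ``b``; passing ``freeze_at``
    evaluates the amplitude once at that voltage instead.
    """
    varr = np.asarray(v, dtype=float)
    vx = constants.v_T / params.z_x * math.log(params.x_out / params.x_in)
    amp = ghk_amplitude(params, freeze_at if freeze_at is not None else varr, b, constants)
    x = params.z_x * (varr - vx) / constants.v_T
    out = amp * (np.exp(b * x) - np.exp((b - 1.0) * x))
    return out.item() if np.isscalar(v) else out


def sinh_current(
    mechanism: TransportMechanism, v, constants: Constants = DEFAULT_CONSTANTS
):
    """Unrectified (b = 1/2) current: ``2 q eta r sinh(x/2)``, pA/um^2.

    Only valid when the mechanism's bias is exactly 1/2, where the
    difference of exponentials collapses to a hyperbolic sine and the
    current is odd about the reversal potential.
    """
    if mechanism.bias != 0.5:
        raise ValueError("sinh form requires bias b = 1/2")
    n, vo = _eta_vo(mechanism, constants)
    x = (n * np.asarray(v, dtype=float) - vo) / constants.v_T
    out = 2.0 * Q_PA_MS * n * mechanism.rate * np.sinh(x / 2.0)
    return out.item() if np.isscalar(v) else out


def rectifier_limit_current(
    mechanism: TransportMechanism, v, constants: Constants = DEFAULT_CONSTANTS
):
    """Fully rectified current at bias 0 or 1, pA/um^2.

    At ``b = 0`` the current ``q eta r [1 - exp(-x)]`` saturates in the
    forward direction (for a K+ channel: outward flow limited at
    ``q r``, the classic inward rectifier); at ``b = 1`` the mirror form
    ``q eta r [exp(x) - 1]`` saturates in the backward direction.
    """
    if mechanism.bias not in (0.0, 1.0):
        raise ValueError("rectifier limit requires bias b = 0 or b = 1")
    n, vo = _eta_vo(mechanism, constants)
    x = (n * np.asarray(v, dtype=float) - vo) / constants.v_T
    if mechanism.bias == 0.0:
        out = Q_PA_MS * n * mechanism.rate * (1.0 - np.exp(-x))
    else:
        out = Q_PA_MS * n * mechanism.rate * (np.exp(x) - 1.0)
    return out.item() if np.isscalar(v) else out


@dataclass(frozen=True)
class NaKPumpParams:
    """Concentration-explicit Na-K ATPase parameters (bias 0 form)."""

    rate: float
    na_out: float
    na_in: float
    k_out: float
    k_in: float
    v_atp: float

    def __post_init__(self) -> None:
        if min(self.na_out, self.na_in, self.k_out, self.k_in) <= 0:
            raise ValueError("concentrations must be strictly positive")


def nak_concentration_form(
    params: NaKPumpParams, v, constants: Constants = DEFAULT_CONSTANTS
):
    """Inward-rectifying Na-K pump current written in concentrations.

    ``q r [1 - ([Na]_0/[Na]_1)^3 ([K]_1/[K]_0)^2 exp((v_ATP - v)/v_T)]``
    (pA/um^2).  Identical to the (eta, v_o) form once
    ``v_NaK = v_ATP + 3 v_Na - 2 v_K`` is composed from the same
    concentrations: the pump current saturates at ``q r`` for
    ``v >> v_NaK`` but grows exponentially below reversal, which is why
    raising intracellular Na+ barely changes the pump rate in a
    depolarised cell.
    """
    varr = np.asarray(v, dtype=float)
    conc = (params.na_out / params.na_in) ** 3 * (params.k_in / params.k_out) ** 2
    out = Q_PA_MS * params.rate * (
        1.0 - conc * np.exp((params.v_atp - varr) / constants.v_T)
    )
    return out.item() if np.isscalar(v) else out
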