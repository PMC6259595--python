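"""Physical constants and unit helpers.

Energies are carried internally in units of kT (dimensionless); the only
places where Joules or millivolts appear are at the boundary of the API.
The thermal voltage ``v_T = kT/q`` is always derived from the temperature,
never stored separately, so the two cannot drift apart.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Boltzmann constant, J/K.
BOLTZMANN_K = 1.380649e-23

#: Elementary charge, C.
ELEMENTARY_Q = 1.602176634e-19

#: Elementary charge expressed in pA*ms.  Multiplying a molecular rate in
#: molecules/ms/um^2 by this factor gives a current density in pA/um^2.
Q_PA_MS = ELEMENTARY_Q * 1e15

#: Faraday constant, C/mol (used to convert molar Gibbs energies to mV).
FARADAY = 96485.33212


@dataclass(frozen=True)
class Constants:
    """Thermodynamic constants at a fixed temperature.

    Parameters
    ----------
    temperature : float
        Absolute temperature in kelvin. Must be positive. The default of
        310 K (37 C) is mammalian body temperature and gives
        ``v_T`` of about 26.71 mV.
    """

    temperature: float = 310.0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError(f"temperature must be > 0 K, got {self.temperature}")

    @property
    def kT(self) -> float:
        """Thermal energy kT in Joules."""
        return BOLTZMANN_K * self.temperature

    @property
    def v_T(self) -> float:
        """Thermal voltage kT/q in mV."""
        return self.kT / ELEMENTARY_Q * 1e3


#: Shared default constants (310 K).
DEFAULT_CONSTANTS = Constants()


def mM_to_uM(x: float) -> float:
    """Convert a concentration from mM to uM."""
    return x * 1e3


def uM_to_mM(x: float) -> float:
    """Convert a concentration from uM to mM."""
    return x * 1e-3
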