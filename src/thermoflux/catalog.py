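"""Catalogue of classic passive and active transport mechanisms.

Twelve textbook mechanisms — four ion channels, three ATPases, two
exchangers and three symporters — expressed as
:class:`~thermoflux.transport.TransportMechanism` templates with
mammalian default concentrations.  Each template's net charge count
``eta`` and reversal parameter ``v_o`` follow from its stoichiometry:

=====================  ====  =============================
mechanism              eta   v_o
=====================  ====  =============================
Cl- channel             1    v_Cl
K+ channel              1    v_K
Na+ channel            -1    -v_Na
Ca2+ channel           -2    -2 v_Ca
Na+-K+ ATPase           1    v_ATP + 3 v_Na - 2 v_K
Ca2+ ATPase             2    v_ATP + 2 v_Ca
H+ ATPase               1    v_ATP + v_H
Na+-Ca2+ exchanger     -1    2 v_Ca - 3 v_Na
Na+-I- symporter       -1    v_I - 2 v_Na
Na+-H+ exchanger        0    v_H - v_Na
K+-Cl- symporter        0    v_K - v_Cl
Na+-K+-Cl- symporter    0    2 v_Cl - v_Na - v_K
=====================  ====  =============================

Default concentrations are chosen so that v_Na = +60 mV and
v_K = -89 mV, matching the values used by the membrane models in
:mod:`thermoflux.membrane`.  Rates reflect the orders-of-magnitude gap
between electrodiffusion through channels and carrier-mediated
translocation.
"""

from __future__ import annotations

import pandas as pd

from .constants import Constants, DEFAULT_CONSTANTS
from .transport import SpeciesMove, TransportMechanism, eta, reversal_vo

__all__ = ["CONCENTRATIONS", "V_ATP_DEFAULT", "catalog", "catalog_names", "catalog_table"]

#: Default transmembrane concentrations (out, in).  mM except Ca2+ in uM.
CONCENTRATIONS: dict[str, tuple[float, float]] = {
    "Na": (145.0, 15.34),       # mM; v_Na ~ +60 mV
    "K": (5.0, 140.0),          # mM; v_K ~ -89 mV
    "Cl": (110.0, 8.0),         # mM; v_Cl ~ -70 mV
    "Ca": (2000.0, 0.1),        # uM; v_Ca ~ +132 mV at rest
    "H": (3.98e-5, 7.94e-5),    # mM; pH 7.4 out / 7.1 in
    "I": (0.005, 0.1),          # mM; iodide accumulated inside
}

#: Default potential equivalent of ATP hydrolysis, mV.
V_ATP_DEFAULT = -450.0

# Transport rates, molecules/ms/um^2: channels ~1 pA unitary current,
# pumps and carriers orders of magnitude slower.
_R_CHANNEL = 6.0e3
_R_PUMP = 0.1
_R_CARRIER = 2.0


def _move(species: str, valence: int, count: int, source: int, dest: int) -> SpeciesMove:
    out, inside = CONCENTRATIONS[species]
    return SpeciesMove(
        name=species, valence=valence, count=count,
        source=source, dest=dest, conc_out=out, conc_in=inside,
    )


def _build_catalog() -> dict[str, TransportMechanism]:
    entries = {
        "Cl channel": TransportMechanism(
            "Cl channel", (_move("Cl", -1, 1, 0, 1),), rate=_R_CHANNEL),
        "K channel": TransportMechanism(
            "K channel", (_move("K", 1, 1, 1, 0),), rate=_R_CHANNEL),
        "Na channel": TransportMechanism(
            "Na channel", (_move("Na", 1, 1, 0, 1),), rate=_R_CHANNEL),
        "Ca channel": TransportMechanism(
            "Ca channel", (_move("Ca", 2, 1, 0, 1),), rate=_R_CHANNEL),
        "Na-K ATPase": TransportMechanism(
            "Na-K ATPase",
            (_move("Na", 1, 3, 1, 0), _move("K", 1, 2, 0, 1)),
            rate=_R_PUMP, delta_ext=1, v_ext=V_ATP_DEFAULT),
        "Ca ATPase": TransportMechanism(
            "Ca ATPase", (_move("Ca", 2, 1, 1, 0),),
            rate=_R_PUMP, delta_ext=1, v_ext=V_ATP_DEFAULT),
        "H ATPase": TransportMechanism(
            "H ATPase", (_move("H", 1, 1, 1, 0),),
            rate=_R_PUMP, delta_ext=1, v_ext=V_ATP_DEFAULT),
        "Na-Ca exchanger": TransportMechanism(
            "Na-Ca exchanger",
            (_move("Na", 1, 3, 0, 1), _move("Ca", 2, 1, 1, 0)),
            rate=_R_CARRIER),
        "Na-I symporter": TransportMechanism(
            "Na-I symporter",
            (_move("Na", 1, 2, 0, 1), _move("I", -1, 1, 0, 1)),
            rate=_R_CARRIER),
        "Na-H exchanger": TransportMechanism(
            "Na-H exchanger",
            (_move("Na", 1, 1, 0, 1), _move("H", 1, 1, 1, 0)),
            rate=_R_CARRIER),
        "K-Cl symporter": TransportMechanism(
            "K-Cl symporter",
            (_move("K", 1, 1, 1, 0), _move("Cl", -1, 1, 1, 0)),
            rate=_R_CARRIER),
        "Na-K-Cl symporter": TransportMechanism(
            "Na-K-Cl symporter",
            (_move("Na", 1, 1, 0, 1), _move("K", 1, 1, 0, 1),
             _move("Cl", -1, 2, 0, 1)),
            rate=_R_CARRIER),
    }
    return entries


_VO_EXPR = {
    "Cl channel": "v_Cl",
    "K channel": "v_K",
    "Na channel": "-v_Na",
    "Ca channel": "-2 v_Ca",
    "Na-K ATPase": "v_ATP + 3 v_Na - 2 v_K",
    "Ca ATPase": "v_ATP + 2 v_Ca",
    "H ATPase": "v_ATP + v_H",
    "Na-Ca exchanger": "2 v_Ca - 3 v_Na",
    "Na-I symporter": "v_I - 2 v_Na",
    "Na-H exchanger": "v_H - v_Na",
    "K-Cl symporter": "v_K - v_Cl",
    "Na-K-Cl symporter": "2 v_Cl - v_Na - v_K",
}

_RATE_RATIO_EXPR = {
    "Cl channel": "([Cl]0/[Cl]1) exp(v/v_T)",
    "K channel": "([K]1/[K]0) exp(v/v_T)",
    "Na channel": "([Na]0/[Na]1) exp(-v/v_T)",
    "Ca channel": "([Ca]0/[Ca]1) exp(-2v/v_T)",
    "Na-K ATPase": "([Na]1/[Na]0)^3 ([K]0/[K]1)^2 exp((v - v_ATP)/v_T)",
    "Ca ATPase": "([Ca]1/[Ca]0) exp((2v - v_ATP)/v_T)",
    "H ATPase": "([H]1/[H]0) exp((v - v_ATP)/v_T)",
    "Na-Ca exchanger": "([Na]0/[Na]1)^3 ([Ca]1/[Ca]0) exp(-v/v_T)",
    "Na-I symporter": "([Na]0/[Na]1)^2 ([I]0/[I]1) exp(-v/v_T)",
    "Na-H exchanger": "([H]1/[H]0) ([Na]0/[Na]1)",
    "K-Cl symporter": "([K]1/[K]0) ([Cl]1/[Cl]0)",
    "Na-K-Cl symporter": "([Na]0/[Na]1) ([K]0/[K]1) ([Cl]0/[Cl]1)^2",
}


def catalog(name: str | None = None):
    """Return the mechanism template(s).

    With no argument, returns the full ``{name: TransportMechanism}``
    dict; with a name, the single named template.

    Raises
    ------
    KeyError
        If the name is not one of the twelve catalogue entries.
    """
    entries = _build_catalog()
    if name is None:
        return entries
    try:
        return entries[name]
    except KeyError:
        raise KeyError(
            f"unknown mechanism {name!r}; known: {sorted(entries)}"
        ) from None


def catalog_names() -> list[str]:
    return list(_build_catalog())


def catalog_table(constants: Constants = DEFAULT_CONSTANTS) -> pd.DataFrame:
    """Catalogue summary: name, eta, v_o (numeric and symbolic), alpha/beta.

    The numeric ``v_o_mV`` column is computed from each template's
    stoichiometry and default concentrations; the expression columns give
    the same quantities symbolically.
    """
    rows = []
    for name, mech in _build_catalog().items():
        rows.append(
            {
                "name": name,
                "eta": eta(mech),
                "v_o_mV": reversal_vo(mech, constants),
                "v_o_expression": _VO_EXPR[name],
                "rate_ratio_expression": _RATE_RATIO_EXPR[name],
            }
        )
    return pd.DataFrame(rows)
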