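"""Gibbs-energy bookkeeping, flux and current for transmembrane transport.

A transport mechanism moves one or more molecular species across a
membrane in a single event (e.g. a Na-K ATPase moves 3 Na+ out and
2 K+ in).  The work for each species follows from its stoichiometry,
direction, valence and the transmembrane concentrations; the sum over
species, plus any external energy source (ATP hydrolysis), gives the
total Gibbs energy of the event.  Forward and backward event rates are
Boltzmann-weighted exponentials of that energy, split by a bias
``b`` in [0, 1] that produces rectification, and the net flux is their
difference.  Electrogenic mechanisms (net charge moved ``eta != 0``)
generate a current ``i = q * eta * flux``.

Compartment convention: 0 = extracellular, 1 = intracellular.  A move
with ``(source, dest) = (1, 0)`` is outward.  Outward movement of
positive charge is a positive current.

Concentrations only ever enter through the ratio ``conc_out/conc_in``,
so any unit may be used as long as both sides of one species share it;
mM for monovalent ions and uM for intracellular Ca2+ are the
conventions used by the built-in catalogue.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .constants import Constants, DEFAULT_CONSTANTS, Q_PA_MS

logger = logging.getLogger(__name__)

__all__ = [
    "SpeciesMove",
    "TransportMechanism",
    "EnergyBreakdown",
    "nernst_potential",
    "atp_potential",
    "delta_G_species",
    "delta_G_total",
    "eta",
    "reversal_vo",
    "rate_ratio",
    "forward_backward_rates",
    "flux",
    "flux_ionic",
    "current",
    "mechanism_from_dict",
    "mechanism_to_dict",
    "load_mechanism_json",
]


def nernst_potential(
    valence: int,
    conc_out: float,
    conc_in: float,
    constants: Constants = DEFAULT_CONSTANTS,
) -> float:
    """Equilibrium (Nernst) potential of an ion, in mV.

    ``(v_T / z) * ln(conc_out / conc_in)``: the transmembrane potential at
    which electrodiffusive flux of the ion vanishes.

    Raises
    ------
    ValueError
        If the valence is zero (uncharged species have no Nernst
        potential) or a concentration is not strictly positive.
    """
    if valence == 0:
        raise ValueError("Nernst potential is undefined for an uncharged species")
    if conc_out <= 0 or conc_in <= 0:
        raise ValueError("concentrations must be strictly positive")
    return constants.v_T / valence * math.log(conc_out / conc_in)


def atp_potential(
    conc_atp_mM: float = 2.0,
    conc_adp_mM: float = 1.33,
    conc_pi_mM: float = 10.0,
    dG0_kJ_per_mol: float = -30.5,
    constants: Constants = DEFAULT_CONSTANTS,
) -> float:
    """Potential equivalent of ATP hydrolysis, ``v_ATP``, in mV.

    ``v_ATP = [dG0 + kT ln([ADP][Pi]/[ATP])] / q`` with intracellular
    concentrations relative to the 1 M standard state.  The defaults
    (2 mM ATP, 1.33 mM ADP, 10 mM Pi, standard free energy
    -30.5 kJ/mol) give approximately -450 mV, the value commonly quoted
    for working cells; v_ATP becomes more negative as the cell keeps its
    ATP/ADP ratio further from equilibrium.
    """
    if conc_atp_mM <= 0 or conc_adp_mM <= 0 or conc_pi_mM <= 0:
        raise ValueError("ATP, ADP and Pi concentrations must be strictly positive")
    ratio_molar = (conc_adp_mM * 1e-3) * (conc_pi_mM * 1e-3) / (conc_atp_mM * 1e-3)
    dG0_mV = dG0_kJ_per_mol * 1e3 / 96485.33212 * 1e3
    return dG0_mV + constants.v_T * math.log(ratio_molar)


@dataclass(frozen=True)
class SpeciesMove:
    """One species' part in a transport event.

    ``count`` molecules of the species move from compartment ``source``
    to ``dest`` (0 = outside, 1 = inside) in each event.
    """

    name: str
    valence: int
    count: int
    source: int
    dest: int
    conc_out: float
    conc_in: float

    def __post_init__(self) -> None:
        if self.source not in (0, 1) or self.dest not in (0, 1):
            raise ValueError("source and dest must be 0 (out) or 1 (in)")
        if self.source == self.dest:
            raise ValueError("source and dest compartments must differ")
        if self.count < 1:
            raise ValueError("count must be a positive integer")
        if self.conc_out <= 0 or self.conc_in <= 0:
            raise ValueError("concentrations must be strictly positive")

    @property
    def direction(self) -> int:
        """``source - dest``: +1 for outward, -1 for inward movement."""
        return self.source - self.dest

    def nernst(self, constants: Constants = DEFAULT_CONSTANTS) -> float:
        """Nernst potential of this species (ions only), mV."""
        return nernst_potential(self.valence, self.conc_out, self.conc_in, constants)


@dataclass(frozen=True)
class TransportMechanism:
    """A complete transport mechanism: moves, rate, bias, external energy.

    Parameters
    ----------
    moves : sequence of SpeciesMove
        The species transported jointly in one event.
    rate : float
        Transport rate ``r`` in molecules/ms/um^2. Channels are orders of
        magnitude faster than carriers and pumps.
    bias : float
        Rectification bias ``b`` in [0, 1]; 1/2 is symmetric, values
        toward 0 favour the backward and toward 1 the forward direction.
    delta_ext : {0, 1, None}
        Whether an external energy source participates.  ``None`` means
        "decide at evaluation time": 1 iff the chemical part of the
        energy is uphill (positive).  ATPase templates pin this to 1.
    v_ext : float
        Potential equivalent of the external energy, mV (``v_ATP`` for
        ATPases).
    """

    name: str
    moves: tuple[SpeciesMove, ...]
    rate: float = 1.0
    bias: float = 0.5
    delta_ext: int | None = 0
    v_ext: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "moves", tuple(self.moves))
        if not self.moves:
            raise ValueError("a mechanism needs at least one species move")
        if self.rate <= 0:
            raise ValueError("rate must be strictly positive")
        if not 0.0 <= self.bias <= 1.0:
            raise ValueError("bias must lie in [0, 1]")
        if self.delta_ext not in (0, 1, None):
            raise ValueError("delta_ext must be 0, 1 or None (auto)")

    @property
    def eta(self) -> int:
        """Net number of elementary charges moved outward per event."""
        return eta(self)

    @property
    def is_electrogenic(self) -> bool:
        return self.eta != 0


@dataclass(frozen=True)
class EnergyBreakdown:
    """Per-species and total Gibbs energies of one transport event (kT)."""

    per_species: Mapping[str, float]
    total_species: float
    external: float
    grand_total: float


def delta_G_species(
    move: SpeciesMove, v: float, constants: Constants = DEFAULT_CONSTANTS
) -> float:
    """Work to move ``count`` molecules from source to dest, in kT.

    ``n (c - d) [ln(conc_out/conc_in) - z v / v_T]``.  For an ion this is
    ``q z n (c - d)(v_s - v) / kT`` with ``v_s`` the Nernst potential, so
    it vanishes at ``v = v_s``; for an uncharged species the potential
    drops out entirely.
    """
    if not math.isfinite(v):
        raise ValueError("membrane potential must be finite")
    return move.count * move.direction * (
        math.log(move.conc_out / move.conc_in) - move.valence * v / constants.v_T
    )


def delta_G_total(
    mechanism: TransportMechanism,
    v: float,
    constants: Constants = DEFAULT_CONSTANTS,
) -> EnergyBreakdown:
    """Total Gibbs energy of one event, including any external source.

    The external term ``delta_ext * q * v_ext`` (in kT) is added when
    ``delta_ext`` is pinned to 1, or, in automatic mode, exactly when the
    summed per-species energy is uphill (> 0).  A pinned ``delta_ext = 1``
    with a downhill chemical energy is allowed but logged, since spending
    external energy on a downhill event is thermodynamically wasteful.
    """
    per = {m.name: delta_G_species(m, v, constants) for m in mechanism.moves}
    total_s = math.fsum(per.values())
    if mechanism.delta_ext is None:
        d_ext = 1 if total_s > 0 else 0
    else:
        d_ext = mechanism.delta_ext
        if d_ext == 1 and total_s <= 0:
            logger.warning(
                "%s: delta_ext pinned to 1 but species energy %.3g kT is not uphill",
                mechanism.name,
                total_s,
            )
    external = d_ext * mechanism.v_ext / constants.v_T
    return EnergyBreakdown(
        per_species=per,
        total_species=total_s,
        external=external,
        grand_total=external + total_s,
    )


def eta(mechanism: TransportMechanism) -> int:
    """Net charge count moved outward per event: sum of n (c-d) z."""
    return sum(m.count * m.direction * m.valence for m in mechanism.moves)


def reversal_vo(
    mechanism: TransportMechanism, constants: Constants = DEFAULT_CONSTANTS
) -> float:
    """Composite reversal parameter ``v_o`` in mV.

    ``v_o = delta_ext * v_ext + sum n z (c - d) v_s`` over the ionic
    moves.  The physical reversal potential of an electrogenic mechanism
    is ``v_o / eta``; for a non-electrogenic mechanism (eta = 0) ``v_o``
    is still returned (it measures the chemical driving force) but there
    is no membrane potential at which the flux reverses, which is logged.
    """
    if any(m.valence == 0 for m in mechanism.moves):
        raise ValueError("v_o requires all moves to be ionic (nonzero valence)")
    d_ext = mechanism.delta_ext if mechanism.delta_ext is not None else (
        1 if delta_G_total(mechanism, 0.0, constants).total_species > 0 else 0
    )
    vo = d_ext * mechanism.v_ext + math.fsum(
        m.count * m.valence * m.direction * m.nernst(constants)
        for m in mechanism.moves
    )
    if eta(mechanism) == 0:
        logger.info("%s is non-electrogenic: v_o has no reversal interpretation",
                    mechanism.name)
    return vo


def rate_ratio(delta_G: float) -> float:
    """Forward/backward rate ratio ``alpha/beta = exp(-delta_G)`` (kT units)."""
    return math.exp(-delta_G)


def forward_backward_rates(
    delta_G: float, r: float, b: float
) -> tuple[float, float]:
    """Boltzmann-weighted event rates ``(alpha, beta)``.

    ``alpha = r exp(-b dG)`` and ``beta = r exp((1-b) dG)`` so that
    ``alpha/beta = exp(-dG)`` holds identically for every ``r`` and ``b``.
    """
    if r <= 0:
        raise ValueError("rate must be strictly positive")
    if not 0.0 <= b <= 1.0:
        raise ValueError("bias must lie in [0, 1]")
    return r * math.exp(-b * delta_G), r * math.exp((1.0 - b) * delta_G)


def flux(
    mechanism: TransportMechanism,
    v: float,
    constants: Constants = DEFAULT_CONSTANTS,
) -> float:
    """Net flux ``alpha - beta`` in molecules/ms/um^2.

    Computed from the concentration-explicit energy, so it is valid for
    any mixture of charged and uncharged species.  Flux always runs down
    the total energy gradient: ``flux * delta_G <= 0``.
    """
    dG = delta_G_total(mechanism, v, constants).grand_total
    a, b_ = forward_backward_rates(dG, mechanism.rate, mechanism.bias)
    return a - b_


def flux_ionic(
    mechanism: TransportMechanism,
    v: float,
    constants: Constants = DEFAULT_CONSTANTS,
) -> float:
    """Net flux via the reversal-parameter form, ions only.

    ``r [exp(b x) - exp((b-1) x)]`` with ``x = (eta v - v_o)/v_T``.  For a
    purely ionic mechanism this is algebraically identical to
    :func:`flux`; it is exposed separately so the identity can be checked
    and because the (eta, v_o) parametrisation is the natural one for
    membrane models.
    """
    x = (eta(mechanism) * v - reversal_vo(mechanism, constants)) / constants.v_T
    b = mechanism.bias
    return mechanism.rate * (math.exp(b * x) - math.exp((b - 1.0) * x))


def current(
    mechanism: TransportMechanism,
    v: float,
    constants: Constants = DEFAULT_CONSTANTS,
) -> float:
    """Current density ``i = q eta flux`` in pA/um^2.

    Zero exactly at the reversal potential ``v_o / eta``; positive when
    net positive charge moves outward.

    Raises
    ------
    ValueError
        If the mechanism is non-electrogenic (eta = 0): it produces flux
        but no current.
    """
    n = eta(mechanism)
    if n == 0:
        raise ValueError(f"{mechanism.name} is non-electrogenic (eta = 0)")
    return Q_PA_MS * n * flux(mechanism, v, constants)


# ---------------------------------------------------------------------------
# JSON (de)serialisation


def mechanism_to_dict(mechanism: TransportMechanism) -> dict:
    return {
        "name": mechanism.name,
        "moves": [
            {
                "species": m.name,
                "z": m.valence,
                "n": m.count,
                "source": m.source,
                "dest": m.dest,
                "conc_out": m.conc_out,
                "conc_in": m.conc_in,
            }
            for m in mechanism.moves
        ],
        "r": mechanism.rate,
        "b": mechanism.bias,
        "delta_ext": mechanism.delta_ext,
        "v_ext": mechanism.v_ext,
    }


def mechanism_from_dict(doc: Mapping) -> TransportMechanism:
    known = {"name", "moves", "r", "b", "delta_ext", "v_ext"}
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"unknown mechanism keys: {sorted(unknown)}")
    moves = tuple(
        SpeciesMove(
            name=m["species"],
            valence=int(m["z"]),
            count=int(m["n"]),
            source=int(m["source"]),
            dest=int(m["dest"]),
            conc_out=float(m["conc_out"]),
            conc_in=float(m["conc_in"]),
        )
        for m in doc["moves"]
    )
    return TransportMechanism(
        name=doc["name"],
        moves=moves,
        rate=float(doc.get("r", 1.0)),
        bias=float(doc.get("b", 0.5)),
        delta_ext=doc.get("delta_ext", 0),
        v_ext=float(doc.get("v_ext", 0.0)),
    )


def load_mechanism_json(path) -> TransportMechanism:
    """Load a mechanism definition from a JSON document."""
    with open(path) as fh:
        return mechanism_from_dict(json.load(fh))
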