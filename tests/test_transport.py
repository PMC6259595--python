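"""Energy bookkeeping, rates, flux and current for transport mechanisms."""

import json
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermoflux import (
    Constants,
    SpeciesMove,
    TransportMechanism,
    atp_potential,
    catalog,
    catalog_names,
    current,
    delta_G_species,
    delta_G_total,
    eta,
    flux,
    flux_ionic,
    forward_backward_rates,
    nernst_potential,
    rate_ratio,
    reversal_vo,
)
from thermoflux.constants import BOLTZMANN_K, ELEMENTARY_Q
from thermoflux.transport import mechanism_from_dict, mechanism_to_dict

C = Constants()


def ion(name, z, n, source, dest, out, inside):
    return SpeciesMove(name, z, n, source, dest, out, inside)


# ---------------------------------------------------------------------------
# Nernst and ATP potentials


class TestNernst:
    def test_equal_concentrations_zero(self):
        assert nernst_potential(1, 5.0, 5.0, C) == 0.0

    def test_tenfold_gradient_matches_closed_form(self):
        # independent closed form: (kT/q) ln 10 at 310 K, in mV
        expected = BOLTZMANN_K * 310.0 / ELEMENTARY_Q * 1e3 * math.log(10.0)
        assert nernst_potential(1, 10.0, 1.0, C) == pytest.approx(expected)
        assert expected == pytest.approx(61.5, abs=0.1)

    def test_valence_scaling(self):
        v1 = nernst_potential(1, 10.0, 1.0, C)
        v2 = nernst_potential(2, 10.0, 1.0, C)
        assert v2 == pytest.approx(v1 / 2)

    @pytest.mark.parametrize("bad", [(0, 1.0, 1.0), (1, 0.0, 1.0), (1, 1.0, -2.0)])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            nernst_potential(*bad, C)


class TestATPPotential:
    def test_default_near_minus_450(self):
        assert atp_potential(constants=C) == pytest.approx(-450.0, abs=1.0)

    def test_log_term_vanishes_at_unit_ratio(self):
        # [ADP][Pi]/[ATP] = 1 M: only the standard term survives
        v = atp_potential(1000.0, 1000.0, 1000.0, dG0_kJ_per_mol=-30.5, constants=C)
        assert v == pytest.approx(-30.5e3 / 96485.33212 * 1e3)

    def test_tenfold_atp_shift(self):
        base = atp_potential(2.0, 1.33, 10.0, constants=C)
        shifted = atp_potential(20.0, 1.33, 10.0, constants=C)
        assert base - shifted == pytest.approx(C.v_T * math.log(10.0))

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ValueError):
            atp_potential(0.0, 1.0, 1.0)


# ---------------------------------------------------------------------------
# Species and total energies


class TestDeltaG:
    def test_ion_vanishes_at_nernst_potential(self):
        k = ion("K", 1, 1, 1, 0, 5.0, 140.0)
        v_k = k.nernst(C)
        assert delta_G_species(k, v_k, C) == pytest.approx(0.0, abs=1e-12)

    def test_uncharged_balanced_is_zero_and_v_independent(self):
        glc = ion("glucose", 0, 1, 0, 1, 5.0, 5.0)
        assert delta_G_species(glc, 0.0, C) == 0.0
        assert delta_G_species(glc, -80.0, C) == 0.0

    def test_inward_sodium_direct_substitution(self):
        # n=1, (c,d)=(0,1), v=0, ratio 10: dG = -(ln 10) kT
        na = ion("Na", 1, 1, 0, 1, 150.0, 15.0)
        assert delta_G_species(na, 0.0, C) == pytest.approx(-math.log(10.0))

    def test_total_is_sum_of_species(self):
        mech = catalog("Na-K-Cl symporter")
        for v in (-90.0, -30.0, 40.0):
            bd = delta_G_total(mech, v, C)
            brute = math.fsum(delta_G_species(m, v, C) for m in mech.moves)
            assert bd.total_species == pytest.approx(brute, rel=1e-14)
            assert bd.grand_total == pytest.approx(bd.external + bd.total_species)

    def test_nak_atpase_zero_at_reversal(self):
        mech = catalog("Na-K ATPase")
        v_rev = reversal_vo(mech, C) / eta(mech)
        assert delta_G_total(mech, v_rev, C).grand_total == pytest.approx(0.0, abs=1e-10)

    def test_kcl_symporter_energy_v_independent(self):
        mech = catalog("K-Cl symporter")
        g1 = delta_G_total(mech, -120.0, C).grand_total
        g2 = delta_G_total(mech, 50.0, C).grand_total
        assert g1 == pytest.approx(g2, rel=1e-14)


# ---------------------------------------------------------------------------
# Rates


class TestRates:
    def test_zero_energy_gives_unit_ratio_and_equal_rates(self):
        assert rate_ratio(0.0) == 1.0
        a, b = forward_backward_rates(0.0, r=3.5, b=0.2)
        assert a == b == 3.5

    def test_one_kT(self):
        assert rate_ratio(1.0) == pytest.approx(math.exp(-1.0))

    @settings(max_examples=200, derandomize=True)
    @given(
        dG=st.floats(-30, 30),
        r=st.floats(1e-6, 1e6),
        b=st.floats(0, 1),
    )
    def test_detailed_balance_for_any_rate_and_bias(self, dG, r, b):
        a, beta = forward_backward_rates(dG, r, b)
        assert a / beta == pytest.approx(rate_ratio(dG), rel=1e-12)

    @settings(max_examples=100, derandomize=True)
    @given(dG=st.floats(-30, 30), b=st.floats(0, 1))
    def test_net_rate_runs_downhill(self, dG, b):
        a, beta = forward_backward_rates(dG, 1.0, b)
        assert (a - beta) * dG <= 1e-12

    def test_spot_check_against_direct_exponentials(self):
        a, beta = forward_backward_rates(2.5, r=7.0, b=0.3)
        assert a == pytest.approx(7.0 * math.exp(-0.75))
        assert beta == pytest.approx(7.0 * math.exp(1.75))


# ---------------------------------------------------------------------------
# Flux and current


IONIC_NAMES = [
    "Cl channel", "K channel", "Na channel", "Ca channel",
    "Na-K ATPase", "Ca ATPase", "H ATPase", "Na-Ca exchanger",
    "Na-I symporter",
]


class TestFlux:
    def test_zero_at_zero_total_energy(self):
        mech = catalog("K channel")
        v_k = reversal_vo(mech, C)
        assert flux(mech, v_k, C) == pytest.approx(0.0, abs=1e-9 * mech.rate)

    def test_kcl_symporter_flux_v_independent(self):
        mech = catalog("K-Cl symporter")
        values = [flux(mech, v, C) for v in (-150.0, -60.0, 0.0, 80.0)]
        assert np.ptp(values) <= 1e-12 * max(1.0, abs(values[0]))

    @pytest.mark.parametrize("name", IONIC_NAMES)
    def test_concentration_and_reversal_forms_agree(self, name):
        mech = catalog(name)
        for v in np.linspace(-150.0, 100.0, 26):
            f1 = flux(mech, v, C)
            f2 = flux_ionic(mech, v, C)
            assert f1 == pytest.approx(f2, rel=1e-10, abs=1e-10 * mech.rate)

    @settings(max_examples=60, derandomize=True)
    @given(v=st.floats(-150, 100), b=st.floats(0, 1))
    def test_flux_runs_down_the_gradient(self, v, b):
        base = catalog("Na-Ca exchanger")
        mech = TransportMechanism(base.name, base.moves, rate=base.rate, bias=b)
        dG = delta_G_total(mech, v, C).grand_total
        assert flux(mech, v, C) * dG <= 1e-9


class TestCurrent:
    def test_zero_at_reversal(self):
        mech = catalog("K channel")
        v_rev = reversal_vo(mech, C) / eta(mech)
        assert current(mech, v_rev, C) == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_bias_gives_odd_current(self):
        mech = catalog("K channel")  # b = 0.5 by default
        v_k = reversal_vo(mech, C)
        for delta in (5.0, 20.0, 60.0):
            assert current(mech, v_k + delta, C) == pytest.approx(
                -current(mech, v_k - delta, C), rel=1e-12
            )

    def test_inward_rectifier_closed_form(self):
        # bias 0 potassium current: q r [1 - exp((v_K - v)/v_T)]
        base = catalog("K channel")
        mech = TransportMechanism(base.name, base.moves, rate=base.rate, bias=0.0)
        v_k = reversal_vo(mech, C)
        q_pa = ELEMENTARY_Q * 1e15
        for v in (-120.0, -60.0, 0.0, 40.0):
            expected = q_pa * mech.rate * (1.0 - math.exp((v_k - v) / C.v_T))
            assert current(mech, v, C) == pytest.approx(expected, rel=1e-12)

    def test_sign_follows_driving_force(self):
        # outward-positive: current sign is that of v - v_rev (v_rev = v_o/eta),
        # for either sign of eta
        for name in ("Na channel", "K channel", "Ca channel"):
            mech = catalog(name)
            v_rev = reversal_vo(mech, C) / eta(mech)
            for v in (-120.0, -30.0, 0.0, 50.0):
                if abs(v - v_rev) > 1e-9:
                    assert math.copysign(1, current(mech, v, C)) == math.copysign(
                        1, v - v_rev
                    ), name

    def test_non_electrogenic_current_rejected(self):
        with pytest.raises(ValueError, match="non-electrogenic"):
            current(catalog("Na-H exchanger"), -60.0, C)

    def test_non_electrogenic_flux_v_independent(self):
        mech = catalog("Na-H exchanger")
        f = [flux(mech, v, C) for v in np.linspace(-100, 100, 11)]
        assert np.allclose(f, f[0], rtol=0, atol=1e-12 * max(1, abs(f[0])))


# ---------------------------------------------------------------------------
# Catalogue


class TestCatalog:
    EXPECTED_ETA = {
        "Cl channel": 1, "K channel": 1, "Na channel": -1, "Ca channel": -2,
        "Na-K ATPase": 1, "Ca ATPase": 2, "H ATPase": 1,
        "Na-Ca exchanger": -1, "Na-I symporter": -1,
        "Na-H exchanger": 0, "K-Cl symporter": 0, "Na-K-Cl symporter": 0,
    }

    def test_twelve_mechanisms(self):
        assert len(catalog_names()) == 12

    @pytest.mark.parametrize("name", list(EXPECTED_ETA))
    def test_eta_matches_stoichiometry_table(self, name):
        assert eta(catalog(name)) == self.EXPECTED_ETA[name]

    def test_reversal_compositions(self):
        def vn(species, z):
            m = next(mv for mv in catalog("Na-K-Cl symporter").moves + catalog(
                "Na-Ca exchanger").moves + catalog("H ATPase").moves + catalog(
                "Na-I symporter").moves if mv.name == species)
            return nernst_potential(z, m.conc_out, m.conc_in, C)

        v_na, v_k, v_cl = vn("Na", 1), vn("K", 1), vn("Cl", -1)
        v_ca, v_h, v_i = vn("Ca", 2), vn("H", 1), vn("I", -1)
        v_atp = catalog("Na-K ATPase").v_ext
        expected = {
            "Cl channel": v_cl,
            "K channel": v_k,
            "Na channel": -v_na,
            "Ca channel": -2 * v_ca,
            "Na-K ATPase": v_atp + 3 * v_na - 2 * v_k,
            "Ca ATPase": v_atp + 2 * v_ca,
            "H ATPase": v_atp + v_h,
            "Na-Ca exchanger": 2 * v_ca - 3 * v_na,
            "Na-I symporter": v_i - 2 * v_na,
            "Na-H exchanger": v_h - v_na,
            "K-Cl symporter": v_k - v_cl,
            "Na-K-Cl symporter": 2 * v_cl - v_na - v_k,
        }
        for name, vo in expected.items():
            assert reversal_vo(catalog(name), C) == pytest.approx(vo, rel=1e-12), name

    def test_rate_ratio_matches_tabulated_expressions(self):
        # symbolic alpha/beta column evaluated numerically per mechanism
        conc = {m.name: (m.conc_out, m.conc_in)
                for mech in catalog().values() for m in mech.moves}
        vT = C.v_T
        v_atp = catalog("Na-K ATPase").v_ext

        def R(s):
            return conc[s][0] / conc[s][1]

        exprs = {
            "Cl channel": lambda v: R("Cl") * math.exp(v / vT),
            "K channel": lambda v: (1 / R("K")) * math.exp(v / vT),
            "Na channel": lambda v: R("Na") * math.exp(-v / vT),
            "Ca channel": lambda v: R("Ca") * math.exp(-2 * v / vT),
            "Na-K ATPase": lambda v: (1 / R("Na")) ** 3 * R("K") ** 2
            * math.exp((v - v_atp) / vT),
            "Ca ATPase": lambda v: (1 / R("Ca")) * math.exp((2 * v - v_atp) / vT),
            "H ATPase": lambda v: (1 / R("H")) * math.exp((v - v_atp) / vT),
            "Na-Ca exchanger": lambda v: R("Na") ** 3 / R("Ca") * math.exp(-v / vT),
            "Na-I symporter": lambda v: R("Na") ** 2 * R("I") * math.exp(-v / vT),
            "Na-H exchanger": lambda v: (1 / R("H")) * R("Na"),
            "K-Cl symporter": lambda v: (1 / R("K")) / R("Cl"),
            "Na-K-Cl symporter": lambda v: R("Na") * R("K") * R("Cl") ** 2,
        }
        for name, expr in exprs.items():
            mech = catalog(name)
            for v in (-90.0, -20.0, 30.0):
                dG = delta_G_total(mech, v, C).grand_total
                assert rate_ratio(dG) == pytest.approx(expr(v), rel=1e-10), name

    def test_unknown_name_raises(self):
        with pytest.raises(KeyError, match="unknown mechanism"):
            catalog("Mg channel")


class TestSerialisation:
    def test_json_round_trip(self, tmp_path):
        mech = catalog("Na-Ca exchanger")
        doc = mechanism_to_dict(mech)
        path = tmp_path / "mech.json"
        path.write_text(json.dumps(doc))
        back = mechanism_from_dict(json.loads(path.read_text()))
        assert back == mech

    def test_unknown_keys_rejected(self):
        doc = mechanism_to_dict(catalog("K channel"))
        doc["conductance"] = 1.0
        with pytest.raises(ValueError, match="unknown mechanism keys"):
            mechanism_from_dict(doc)

    def test_invalid_moves_rejected(self):
        with pytest.raises(ValueError):
            SpeciesMove("X", 1, 1, 0, 0, 1.0, 1.0)  # same compartments
        with pytest.raises(ValueError):
            SpeciesMove("X", 1, 0, 0, 1, 1.0, 1.0)  # zero count
        with pytest.raises(ValueError):
            TransportMechanism("empty", ())
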