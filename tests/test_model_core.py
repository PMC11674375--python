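import math

import numpy as np
import pytest
import yaml
from hypothesis import given, settings
from hypothesis import strategies as st
from importlib import resources

import glycosim as g
from glycosim.errors import (
    ConfigurationError,
    ConsistencyError,
    ValidationError,
)
from glycosim.model import (
    REFERENCE_DYNAMIC_SET,
    KineticModel,
    Metabolite,
    Modifier,
    RateLaw,
    Reaction,
    model_from_dict,
)


def _reference_doc():
    ref = resources.files("glycosim.data").joinpath("reference_model.yaml")
    return yaml.safe_load(ref.read_text())


# ---------------------------------------------------------------------------
# build_reference_model
# ---------------------------------------------------------------------------

class TestBuildReferenceModel:
    def test_dynamic_set_is_the_21_species(self, reference_model):
        assert set(reference_model.dynamic_ids) == REFERENCE_DYNAMIC_SET
        assert len(reference_model.dynamic_ids) == 21

    def test_cofactors_clamped_not_dynamic(self, reference_model):
        for cof in ("NAD", "NADH", "ADP", "ATP"):
            assert cof not in reference_model.dynamic_ids
            assert cof in reference_model.clamp_values
            assert reference_model.metabolite_index[cof].role == "clamped"

    def test_contains_shunt_reactions(self, reference_model):
        bpgm = reference_model.reaction_index["BPGM"]
        assert bpgm.stoichiometry == {"13P2G": -1, "23P2G": 1}
        phos = reference_model.reaction_index["BPG_PHOSPHATASE"]
        assert phos.stoichiometry == {"23P2G": -1, "3PG": 1, "P": 1}

    def test_pyruvate_consumers_restricted(self, reference_model):
        consumers = {
            r.id
            for r in reference_model.reactions
            if r.stoichiometry.get("Pyr", 0) < 0
        }
        assert consumers <= {"LDH", "PC"}

    def test_missing_km_is_configuration_error_naming_reaction(self):
        doc = _reference_doc()
        for rxn in doc["reactions"]:
            if rxn["id"] == "HK":
                del rxn["rate_law"]["km"]["Glc"]
        with pytest.raises(ConfigurationError, match="HK"):
            g.build_reference_model(doc)

    def test_missing_units_rejected(self):
        doc = _reference_doc()
        doc["reactions"][1]["rate_law"]["vmax"] = {"value": 0.9}
        with pytest.raises(ConfigurationError, match="unit"):
            g.build_reference_model(doc)

    def test_carbon_imbalance_rejected(self):
        doc = _reference_doc()
        for rxn in doc["reactions"]:
            if rxn["id"] == "TPI":
                rxn["stoichiometry"] = {"DHAP": -1, "GAP": 2}
        with pytest.raises(ValidationError, match="TPI"):
            g.build_reference_model(doc)

    def test_haldane_violation_rejected(self):
        doc = _reference_doc()
        for rxn in doc["reactions"]:
            if rxn["id"] == "GPI":
                rxn["rate_law"]["vmax_reverse"] = {"value": 1.0, "unit": "mM/min"}
        with pytest.raises(ValidationError, match="Haldane"):
            g.build_reference_model(doc)

    def test_coupling_toggles_strip_modifiers(self):
        on = g.build_reference_model()
        off = g.build_reference_model(couplings={"bpg_hk": False})
        mods_on = [m.metabolite for m in on.reaction_index["HK"].rate_law.modifiers]
        mods_off = [m.metabolite for m in off.reaction_index["HK"].rate_law.modifiers]
        assert "23P2G" in mods_on
        assert "23P2G" not in mods_off


# ---------------------------------------------------------------------------
# reaction_rate
# ---------------------------------------------------------------------------

def _mm_irrev(vmax=1.0, km=0.5):
    return Reaction(
        id="R",
        stoichiometry={"A": -1, "B": 1},
        rate_law=RateLaw(
            "michaelis_menten_irreversible", vmax_forward=vmax, km={"A": km}
        ),
    )


class TestReactionRate:
    def test_irreversible_mm_zero_substrate(self):
        assert g.reaction_rate(_mm_irrev(), {"A": 0.0, "B": 1.0}) == 0.0

    def test_irreversible_mm_half_saturation(self):
        assert g.reaction_rate(_mm_irrev(2.0, 0.5), {"A": 0.5, "B": 0.0}) == pytest.approx(1.0)

    def test_mass_action_zero_at_equilibrium(self):
        rxn = Reaction(
            id="R",
            stoichiometry={"A": -1, "B": 1},
            rate_law=RateLaw("mass_action_reversible", vmax_forward=3.0, keq=2.5),
        )
        assert g.reaction_rate(rxn, {"A": 1.0, "B": 2.5}) == pytest.approx(0.0, abs=1e-15)
        assert g.reaction_rate(rxn, {"A": 0.4, "B": 1.0}) == pytest.approx(0.0, abs=1e-15)

    def test_reversible_mm_hand_evaluated(self):
        # independent hand evaluation of the closed-form expression
        vf, keq, km_s, km_p = 2.0, 4.0, 0.5, 1.5
        vr = vf * km_p / (km_s * keq)  # Haldane
        s, p = 0.3, 0.2
        gs, gp = s / km_s, p / km_p
        expected = (vf * gs - vr * gp) / ((1 + gs) + (1 + gp) - 1)
        rxn = Reaction(
            id="R",
            stoichiometry={"S": -1, "P": 1},
            rate_law=RateLaw(
                "michaelis_menten_reversible",
                vmax_forward=vf,
                keq=keq,
                km={"S": km_s, "P": km_p},
            ),
        )
        assert g.reaction_rate(rxn, {"S": s, "P": p}) == pytest.approx(expected, rel=1e-14)

    def test_reversible_mm_zero_at_equilibrium(self):
        rxn = Reaction(
            id="R",
            stoichiometry={"S": -1, "P": 1},
            rate_law=RateLaw(
                "michaelis_menten_reversible",
                vmax_forward=2.0,
                keq=4.0,
                km={"S": 0.5, "P": 1.5},
            ),
        )
        # [P]/[S] == Keq
        assert g.reaction_rate(rxn, {"S": 0.7, "P": 2.8}) == pytest.approx(0.0, abs=1e-15)

    def test_transporter_zero_at_equal_concentrations(self):
        rxn = Reaction(
            id="T",
            stoichiometry={"Out": -1, "In": 1},
            rate_law=RateLaw(
                "transporter_facilitated",
                vmax_forward=5.0,
                km={"Out": 2.0, "In": 2.0},
            ),
        )
        assert g.reaction_rate(rxn, {"In": 1.3}, {"Out": 1.3}) == 0.0
        assert g.reaction_rate(rxn, {"In": 0.5}, {"Out": 1.3}) > 0

    def test_unresolvable_metabolite_raises(self):
        with pytest.raises(ConsistencyError, match="A"):
            g.reaction_rate(_mm_irrev(), {"B": 1.0})

    def test_competitive_inhibitor_strictly_decreases_rate(self):
        rxn = _mm_irrev(2.0, 0.5)
        rxn.rate_law.modifiers.append(
            Modifier(metabolite="I", kind="competitive_inhibitor", constant=1.0)
        )
        rates = [
            g.reaction_rate(rxn, {"A": 0.5, "B": 0.0, "I": i})
            for i in (0.0, 0.1, 1.0, 10.0)
        ]
        assert rates[0] == pytest.approx(1.0)
        assert all(a > b > 0 for a, b in zip(rates, rates[1:]))

    def test_allosteric_activator_saturates(self):
        rxn = _mm_irrev(2.0, 0.5)
        rxn.rate_law.modifiers.append(
            Modifier(metabolite="X", kind="allosteric_activator", constant=1.0, hill=2.0)
        )
        r0 = g.reaction_rate(rxn, {"A": 0.5, "B": 0.0, "X": 0.0})
        r_half = g.reaction_rate(rxn, {"A": 0.5, "B": 0.0, "X": 1.0})
        r_big = g.reaction_rate(rxn, {"A": 0.5, "B": 0.0, "X": 100.0})
        assert r0 == 0.0
        assert r_half == pytest.approx(0.5)
        assert r_big < 1.0 and r_big == pytest.approx(1.0, rel=1e-3)

    @settings(max_examples=50, deadline=None)
    @given(
        s=st.floats(0.0, 50.0),
        p=st.floats(0.0, 50.0),
        c=st.floats(1e-3, 1e3),
    )
    def test_rate_proportional_to_vmax(self, s, p, c):
        rxn = Reaction(
            id="R",
            stoichiometry={"S": -1, "P": 1},
            rate_law=RateLaw(
                "michaelis_menten_reversible",
                vmax_forward=2.0,
                keq=4.0,
                km={"S": 0.5, "P": 1.5},
            ),
        )
        v1 = g.reaction_rate(rxn, {"S": s, "P": p})
        rxn.rate_law.vmax_forward *= c
        v2 = g.reaction_rate(rxn, {"S": s, "P": p})
        assert v2 == pytest.approx(c * v1, rel=1e-12, abs=1e-300)


class TestHKInhibition:
    def test_hk_flux_strictly_decreasing_in_23p2g(self, reference_model, reference_steady):
        hk = reference_model.reaction_index["HK"]
        state = dict(reference_steady.concentrations)
        fluxes = []
        for bpg in (0.0, 0.5, 1.0, 2.0, 4.0, 8.0):
            state["23P2G"] = bpg
            fluxes.append(g.reaction_rate(hk, state, reference_model.clamp_values))
        assert all(a > b > 0 for a, b in zip(fluxes, fluxes[1:]))


# ---------------------------------------------------------------------------
# rhs
# ---------------------------------------------------------------------------

class TestRhs:
    def test_all_vmax_zero_gives_zero_vector(self, reference_model):
        m = reference_model.copy()
        for r in m.reactions:
            r.rate_law.vmax_forward = 0.0
            if r.rate_law.vmax_reverse is not None:
                r.rate_law.vmax_reverse = 0.0
        dx = g.rhs(m, m.initial_state())
        assert np.all(dx == 0.0)

    def test_single_reaction_stoichiometry(self):
        model = KineticModel(
            metabolites=[
                Metabolite("A", "A", "dynamic", 1, 2.0),
                Metabolite("B", "B", "dynamic", 1, 0.5),
            ],
            reactions=[_mm_irrev(vmax=3.0, km=1.0)],
            clamp_values={},
        )
        model.validate()
        r = g.reaction_rate(model.reactions[0], {"A": 2.0, "B": 0.5})
        dx = g.rhs(model, np.array([2.0, 0.5]))
        assert dx == pytest.approx([-r, r])

    def test_toy_chain_zero_rhs_at_analytic_steady_state(self, toy_spec, toy_model):
        x_star = np.array(toy_spec.steady_state())
        dx = g.rhs(toy_model, x_star)
        assert np.max(np.abs(dx)) < 1e-10

    @settings(max_examples=25, deadline=None)
    @given(c=st.floats(1e-2, 1e2), seed=st.integers(0, 1000))
    def test_rhs_homogeneous_in_vmax(self, reference_model, c, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0.01, 5.0, size=len(reference_model.dynamic_ids))
        base = g.rhs(reference_model, x)
        scaled_model = reference_model.copy()
        scaled_model.scale_vmax({r.id: c for r in scaled_model.reactions})
        scaled = g.rhs(scaled_model, x)
        np.testing.assert_allclose(scaled, c * base, rtol=1e-12)


# ---------------------------------------------------------------------------
# carbon bookkeeping
# ---------------------------------------------------------------------------

class TestCarbonBalance:
    def test_zero_flux_zero_residual(self, reference_model):
        v = np.zeros(len(reference_model.reactions))
        assert g.carbon_balance_residual(reference_model, v) == 0.0

    def test_balanced_model_residual_is_identically_zero(self, reference_model):
        rng = np.random.default_rng(0)
        v = rng.normal(size=len(reference_model.reactions))
        assert abs(g.carbon_balance_residual(reference_model, v)) < 1e-12

    def test_steady_state_boundary_carbon_closes(self, reference_model, reference_steady):
        inflow = g.exchange_carbon_inflow(
            reference_model, reference_steady.reaction_fluxes
        )
        vmax_exch = max(abs(v) for v in reference_steady.exchange_fluxes.values())
        assert abs(inflow) < 1e-6 * 6 * vmax_exch

    def test_glc_lac_carbon_bookkeeping(self, reference_model, reference_steady):
        # all non-Glc/Lac boundary carbon flows, counted explicitly
        v_glc = reference_steady.exchange_fluxes["Glc"]
        v_lac = reference_steady.exchange_fluxes["Lac"]
        v_fru = reference_steady.exchange_fluxes["Fru"]
        v_mal = reference_steady.exchange_fluxes["Mal"]
        v_co2 = reference_steady.flux("PEPCK") - reference_steady.flux("PC")
        assert 6 * v_glc + 6 * v_fru + 4 * v_mal == pytest.approx(
            3 * v_lac + v_co2, rel=1e-9
        )

    def test_constructed_defect_reports_introduced_imbalance(self):
        # A (1 carbon) -> B (2 carbons): +1 carbon created per unit flux
        model = KineticModel(
            metabolites=[
                Metabolite("A", "A", "dynamic", 1, 1.0),
                Metabolite("B", "B", "dynamic", 2, 1.0),
            ],
            reactions=[
                Reaction(
                    id="BAD",
                    stoichiometry={"A": -1, "B": 1},
                    rate_law=RateLaw(
                        "mass_action_reversible", vmax_forward=1.0, vmax_reverse=0.0
                    ),
                )
            ],
            clamp_values={},
        )
        assert g.carbon_balance_residual(model, np.array([1.0])) == pytest.approx(1.0)
        with pytest.raises(ValidationError, match="BAD"):
            model.validate()


class TestEquilibriumConsistency:
    def test_every_reversible_reference_law_is_zero_at_its_keq(self, reference_model):
        for rxn in reference_model.reactions:
            law = rxn.rate_law
            if law.form not in (
                "michaelis_menten_reversible",
                "mass_action_reversible",
            ) or not (law.keq or law.vmax_reverse):
                continue
            if rxn.reverse_vmax() == 0:
                continue
            # start from valid concentrations so modifier lookups resolve;
            # modifiers never shift the equilibrium point
            conc = reference_model.state_dict(reference_model.initial_state())
            conc.update(reference_model.clamp_values)
            if law.form == "michaelis_menten_reversible":
                for m in rxn.substrates:
                    if m in law.km:
                        conc[m] = law.km[m]
                prods = [m for m in rxn.products if m in law.km]
                for m in prods:
                    conc[m] = law.km[m]
                conc[prods[0]] = law.km[prods[0]] * (
                    law.vmax_forward / rxn.reverse_vmax()
                )
            else:
                for m in rxn.substrates:
                    conc[m] = 1.0
                for m in rxn.products:
                    conc[m] = 1.0
                conc[rxn.products[0]] = law.vmax_forward / rxn.reverse_vmax()
            v = g.reaction_rate(rxn, conc, reference_model.clamp_values)
            assert v == pytest.approx(0.0, abs=1e-12 * law.vmax_forward), rxn.id
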