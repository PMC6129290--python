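"""Model I/O, mutation operations and the FBA solver."""

import numpy as np
import pytest

from flexcop import (
    FluxCoupling,
    Metabolite,
    ModelSchemaError,
    Reaction,
    StoichModel,
    add_growth_coupled_secretion,
    partition_fixed_carbon,
    read_model,
    set_bounds,
    solve_fba,
    toy_phototroph,
    toy_t1,
    toy_t1_with_secretion,
    write_model,
)
from oracles import fba_vertex_oracle

import flexcop
from pathlib import Path

PACKAGED_T1 = Path(flexcop.__file__).parent / "data" / "t1.json"


# ---------------------------------------------------------------------------
# document I/O
# ---------------------------------------------------------------------------

class TestModelIO:
    def test_packaged_t1_round_trip(self, tmp_path):
        model = read_model(PACKAGED_T1)
        assert model.objective == "GROWTH"
        assert {m.id for m in model.metabolites} == {"glc_e", "co2_e"}
        # write -> read is identity
        out = tmp_path / "t1.json"
        write_model(model, out)
        again = read_model(out)
        assert again == model

    def test_write_read_identity_on_coupled_model(self, tmp_path):
        model = add_growth_coupled_secretion(toy_t1_with_secretion(), "SECRETE", 0.5)
        out = tmp_path / "m.json"
        write_model(model, out)
        assert read_model(out) == model

    def test_undeclared_metabolite_names_reaction(self):
        doc = {
            "metabolites": [{"id": "a", "compartment": "internal"}],
            "reactions": [{"id": "R1", "stoich": {"X9": 1}, "lb": 0, "ub": 1}],
            "objective": "R1",
        }
        with pytest.raises(ModelSchemaError, match="R1.*X9"):
            read_model(doc)

    def test_missing_objective_rejected(self):
        doc = {
            "metabolites": [],
            "reactions": [{"id": "R1", "stoich": {}, "lb": 0, "ub": 1}],
        }
        with pytest.raises(ModelSchemaError):
            read_model(doc)

    def test_sbml_fbc_import_matches_native_fba(self, tmp_path):
        """A model written as SBML (via cobrapy) imports with the same
        growth optimum as the native representation."""
        cobra = pytest.importorskip("cobra")
        cm = cobra.Model("mini")
        glc = cobra.Metabolite("glc_e", compartment="e")
        ex = cobra.Reaction("EX_glc")
        ex.add_metabolites({glc: -1})
        ex.lower_bound, ex.upper_bound = -10, 0
        gr = cobra.Reaction("GROWTH")
        gr.add_metabolites({glc: -10})
        gr.lower_bound, gr.upper_bound = 0, 1000
        cm.add_reactions([ex, gr])
        cm.objective = "GROWTH"
        path = tmp_path / "mini.xml"
        cobra.io.write_sbml_model(cm, str(path))
        model = read_model(path, dialect="sbml-fbc")
        sol = solve_fba(model)
        assert sol.ok
        assert sol.objective_value == pytest.approx(1.0, abs=1e-9)
        # cobra itself as independent cross-check on the same document
        assert cm.optimize().objective_value == pytest.approx(
            sol.objective_value, abs=1e-9
        )


# ---------------------------------------------------------------------------
# FBA
# ---------------------------------------------------------------------------

class TestSolveFBA:
    def test_t1_growth_rate(self, t1):
        sol = solve_fba(t1)
        assert sol.ok
        assert sol.objective_value == pytest.approx(1.0, abs=1e-9)

    def test_no_carbon_no_growth(self, t1):
        starved = set_bounds(t1, "EX_glc", 0, 0)
        sol = solve_fba(starved)
        assert sol.ok
        assert sol.objective_value == pytest.approx(0.0, abs=1e-12)

    def test_forced_flux_beyond_capacity_is_infeasible(self, t1):
        # CO2 export can be at most 12 * mu = 12; forcing 20 is impossible
        broken = set_bounds(t1, "EX_co2", 20, 30)
        sol = solve_fba(broken)
        assert sol.status == "infeasible"
        assert not sol.ok

    def test_solution_satisfies_mass_balance_and_bounds(self, t1_secreting):
        model = add_growth_coupled_secretion(t1_secreting, "SECRETE", 0.3)
        sol = solve_fba(model)
        S, _, rxn_ids = model.stoichiometric_matrix()
        v = np.array([sol.fluxes[r] for r in rxn_ids])
        assert np.max(np.abs(S @ v)) <= 1e-6
        for rxn in model.reactions:
            assert rxn.lb - 1e-9 <= sol.fluxes[rxn.id] <= rxn.ub + 1e-9

    @pytest.mark.parametrize("builder,mutate", [
        (toy_t1, None),
        (toy_t1_with_secretion, None),
        (toy_t1_with_secretion, lambda m: add_growth_coupled_secretion(m, "SECRETE", 0.5)),
        (toy_t1_with_secretion, lambda m: add_growth_coupled_secretion(m, "SECRETE", 2.0)),
        (toy_phototroph, None),
        (toy_phototroph, lambda m: partition_fixed_carbon(m, "FIX", "SUC_EXPORT", 0.4)),
        (toy_phototroph, lambda m: partition_fixed_carbon(m, "FIX", "SUC_EXPORT", 0.9)),
    ])
    def test_agrees_with_vertex_enumeration_oracle(self, builder, mutate):
        model = builder()
        if mutate is not None:
            model = mutate(model)
        sol = solve_fba(model)
        oracle = fba_vertex_oracle(model)
        assert sol.ok and oracle is not None
        assert sol.objective_value == pytest.approx(oracle, abs=1e-9)

    def test_parsimonious_flux_vector_is_mass_balanced(self, t1_secreting):
        sol = solve_fba(t1_secreting, parsimonious=True)
        assert sol.ok
        S, _, rxn_ids = t1_secreting.stoichiometric_matrix()
        v = np.array([sol.fluxes[r] for r in rxn_ids])
        assert np.max(np.abs(S @ v)) <= 1e-6
        assert sol.objective_value == pytest.approx(1.0, abs=1e-9)


# ---------------------------------------------------------------------------
# mutation operations
# ---------------------------------------------------------------------------

class TestSetBounds:
    def test_stores_new_bounds(self, t1):
        m = set_bounds(t1, "EX_glc", -3.1, 0)
        assert m.reaction("EX_glc").lb == -3.1
        assert t1.reaction("EX_glc").lb == -10  # original untouched

    def test_idempotent(self, t1):
        m1 = set_bounds(t1, "EX_glc", -3.1, 0)
        m2 = set_bounds(m1, "EX_glc", -3.1, 0)
        assert m1 == m2

    def test_inverted_bounds_rejected(self, t1):
        with pytest.raises(ValueError):
            set_bounds(t1, "EX_glc", 5, 3)

    def test_unknown_reaction_rejected(self, t1):
        with pytest.raises(KeyError):
            set_bounds(t1, "NOPE", 0, 1)


class TestGrowthCoupledSecretion:
    def test_secretion_tax_reduces_growth(self, t1_secreting):
        # each unit of growth now exports 0.5 product at 1 glc apiece:
        # 10 mu + 0.5 mu <= 10  ->  mu = 10/10.5
        m = add_growth_coupled_secretion(t1_secreting, "SECRETE", 0.5)
        sol = solve_fba(m)
        assert sol.objective_value == pytest.approx(10 / 10.5, abs=1e-9)
        assert sol.fluxes["SECRETE"] == pytest.approx(0.5 * sol.objective_value, abs=1e-9)

    def test_zero_coupling_is_identity(self, t1_secreting):
        base = solve_fba(t1_secreting).objective_value
        m = add_growth_coupled_secretion(t1_secreting, "SECRETE", 0.0)
        assert solve_fba(m).objective_value == pytest.approx(base, abs=1e-12)

    def test_unknown_reaction_and_negative_k(self, t1_secreting):
        with pytest.raises(KeyError):
            add_growth_coupled_secretion(t1_secreting, "NOPE", 0.5)
        with pytest.raises(ValueError):
            add_growth_coupled_secretion(t1_secreting, "SECRETE", -0.1)

    def test_growth_monotone_nonincreasing_in_k(self, t1_secreting):
        mus = [
            solve_fba(
                add_growth_coupled_secretion(t1_secreting, "SECRETE", k)
            ).objective_value
            for k in (0.0, 0.25, 0.5, 1.0, 2.0, 4.0)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(mus, mus[1:]))


class TestPartitionFixedCarbon:
    def test_carbon_split(self, phototroph):
        m = partition_fixed_carbon(phototroph, "FIX", "SUC_EXPORT", 0.4)
        sol = solve_fba(m)
        exported_carbon = 12 * sol.fluxes["EX_suc"]
        assert exported_carbon == pytest.approx(0.4 * sol.fluxes["FIX"], abs=1e-9)
        assert sol.fluxes["FIX"] == pytest.approx(10.0, abs=1e-9)
        assert exported_carbon == pytest.approx(4.0, abs=1e-9)

    def test_zero_partition_is_identity(self, phototroph):
        base = solve_fba(phototroph).objective_value
        m = partition_fixed_carbon(phototroph, "FIX", "SUC_EXPORT", 0.0)
        sol = solve_fba(m)
        assert sol.objective_value == pytest.approx(base, abs=1e-12)
        assert sol.fluxes["EX_suc"] == pytest.approx(0.0, abs=1e-12)

    def test_full_partition_rejected(self, phototroph):
        with pytest.raises(ValueError):
            partition_fixed_carbon(phototroph, "FIX", "SUC_EXPORT", 1.0)

    def test_missing_carbon_annotation_rejected(self):
        model = StoichModel(
            metabolites=[
                Metabolite("a", compartment="internal"),
                Metabolite("b_e", compartment="external"),
            ],
            reactions=[
                Reaction("MAKE", {"a": 1}, lb=0, ub=5),
                Reaction("EXPORT", {"a": -1, "b_e": 1}, lb=0),
                Reaction("EX_b", {"b_e": -1}, lb=0, exchange=True),
                Reaction("GROW", {"a": -1}, lb=0),
            ],
            objective="GROW",
        )
        with pytest.raises(ModelSchemaError, match="carbon"):
            partition_fixed_carbon(model, "MAKE", "EXPORT", 0.3)

    def test_growth_monotone_nonincreasing_in_p(self, phototroph):
        mus = [
            solve_fba(
                partition_fixed_carbon(phototroph, "FIX", "SUC_EXPORT", p)
            ).objective_value
            for p in (0.0, 0.2, 0.4, 0.6, 0.8, 0.95)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(mus, mus[1:]))


class TestSchemaValidation:
    def test_exchange_must_touch_one_external_metabolite(self):
        with pytest.raises(ModelSchemaError, match="exchange"):
            StoichModel(
                metabolites=[Metabolite("a", compartment="internal")],
                reactions=[Reaction("EX_a", {"a": -1}, exchange=True)],
                objective="EX_a",
            )

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ModelSchemaError, match="duplicate"):
            StoichModel(
                metabolites=[
                    Metabolite("a", compartment="external"),
                    Metabolite("a", compartment="external"),
                ],
                reactions=[Reaction("R", {"a": 1})],
                objective="R",
            )

    def test_coupling_must_reference_existing_reactions(self, t1):
        with pytest.raises(ModelSchemaError):
            StoichModel(
                metabolites=list(t1.metabolites),
                reactions=list(t1.reactions),
                objective="GROWTH",
                couplings=[FluxCoupling("GROWTH", "NOPE", 1.0)],
            )
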