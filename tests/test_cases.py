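"""Packaged case bundles, the randomized-community generator, the
download-gated recipes and the CLI."""

import dataclasses

import numpy as np
import pytest
from click.testing import CliRunner

from flexcop import (
    ConsortiumConfig,
    classify_profile,
    effective_growth_rate,
    evaluate_config,
    make_auxotroph_ring_toy,
    make_case,
    make_overflow_toy,
    metric_score,
    real_case_recipe,
    run_exhaustive,
    run_smbo,
    SearchBudget,
    simulate,
    subspace,
)
from flexcop.cases import random_community
from flexcop.cli import main as cli_main
from flexcop.configspace import apply_config


class TestProducerConsumerToy:
    def test_no_partition_no_cross_feeding(self, toy1_bundle):
        """With the secretion fraction at zero the consumer never sees
        sucrose: no growth, no product."""
        from flexcop import partition_fixed_carbon

        models = dict(toy1_bundle.models)
        models["synecho"] = partition_fixed_carbon(
            models["synecho"], "FIX", "SUC_EXPORT", 0.0
        )
        layout = toy1_bundle.layout_template.copy()
        layout.horizon = 20.0
        trace = simulate(models, layout, seed=0)
        assert trace.final_concentration("pha_e") == 0.0
        assert trace.final_biomass("KT") == pytest.approx(
            layout.initial_biomass["KT"], rel=1e-12
        )

    def test_nitrogen_free_medium_yields_product_without_growth(self, toy1_bundle):
        """With no ammonium the consumer cannot grow, but the lexicographic
        product stage still converts the available sucrose."""
        config = ConsortiumConfig({"sucrPer": 40.0, "synecho": 2.0, "KT": 0.2, "NH4": 0.5})
        models, layout = apply_config(
            config, toy1_bundle.space, toy1_bundle.models, toy1_bundle.layout_template
        )
        layout.medium["nh4_e"] = 0.0
        layout.horizon = 20.0
        trace = simulate(models, layout, seed=0)
        assert trace.final_biomass("KT") == pytest.approx(0.2, rel=1e-12)
        assert trace.final_concentration("pha_e") > 0.1

    def test_selftest_properties(self, toy1_bundle):
        assert toy1_bundle.selftest() == [
            "zero_partition_exports_nothing",
            "default_config_simulates",
        ]

    def test_smbo_agrees_with_exhaustive_oracle(self):
        """Guided search with a quarter of the space as budget finds the
        exhaustive optimum in >= 19 of 20 seeded runs on a desk-scale
        sweep of the secretion/ratio/ammonium sub-space (96
        configurations, 40 h horizon)."""
        from flexcop import make_producer_consumer_toy

        bundle = make_producer_consumer_toy(horizon=40.0, dt=0.5)
        fitness = dataclasses.replace(bundle.fitness, horizon=40.0)
        space = subspace(bundle.space, {"KT": (0.05,), "NH4": (0.5, 3.5, 7.0)})
        assert space.size() == 96

        def objective(config, seed):
            return evaluate_config(
                config, space, bundle.models, bundle.layout_template,
                fitness, n_replicates=1, base_seed=seed,
            ).mean

        target = run_exhaustive(space, objective).incumbent
        budget = space.size() // 4
        hits = sum(
            run_smbo(space, objective,
                     SearchBudget(max_evaluations=budget, seed=s, initial_random=6)
                     ).incumbent == target
            for s in range(20)
        )
        assert hits >= 19


class TestAuxotrophRingToy:
    def test_mutual_starvation_without_cross_feeding(self, toy2_bundle):
        assignment = dict(toy2_bundle.space.default_config().assignment)
        for i in range(1, 5):
            assignment[f"k{i}"] = 0.0
        models, layout = apply_config(
            ConsortiumConfig(assignment), toy2_bundle.space,
            toy2_bundle.models, toy2_bundle.layout_template,
        )
        trace = simulate(models, layout, seed=0)
        for s in trace.strains:
            # only the seed amino acids are consumable: growth stalls
            assert trace.final_biomass(s) < 2 * trace.biomass[s][0]

    def test_symmetric_ring_equal_growth(self, toy2_bundle):
        trace = toy2_bundle.simulate_default(seed=0)
        rates = [effective_growth_rate(trace, s) for s in trace.strains]
        assert max(rates) - min(rates) < 1e-6
        assert min(rates) > 0.1

    def test_removing_a_strain_starves_its_dependent(self, toy2_bundle):
        models = {s: m for s, m in toy2_bundle.models.items() if s != "Ec1"}
        config = toy2_bundle.space.default_config()
        all_models, layout = apply_config(
            config, toy2_bundle.space, toy2_bundle.models, toy2_bundle.layout_template
        )
        del all_models["Ec1"]
        layout.initial_biomass.pop("Ec1")
        trace = simulate(all_models, layout, seed=0)
        # Ec2 needs amino acid 2, secreted only by Ec1: it stalls at the seed
        assert trace.final_biomass("Ec2") < 2 * trace.biomass["Ec2"][0]

    def test_stability_fitness_maximal_at_symmetric_high_coupling(self):
        """On a two-strain ring with coupling grid {0.5, 1.5}^2 the maximin
        growth-rate fitness peaks exactly at the symmetric sustainable
        configuration."""
        bundle = make_auxotroph_ring_toy(n=2, horizon=8.0)
        space = subspace(bundle.space, {
            "Ec1": (0.1,), "Ec2": (0.1,),
            "k1": (0.5, 1.5), "k2": (0.5, 1.5),
        })

        def objective(config, seed):
            return evaluate_config(
                config, space, bundle.models, bundle.layout_template,
                bundle.fitness, n_replicates=1, base_seed=seed,
            ).mean

        result = run_exhaustive(space, objective)
        assert result.incumbent["k1"] == result.incumbent["k2"] == 1.5


class TestOverflowToy:
    def test_identical_phenotypes_trace_identically_any_seed(self, toy3_bundle):
        config = toy3_bundle.space.default_config()
        models, layout = apply_config(
            config, toy3_bundle.space, toy3_bundle.models, toy3_bundle.layout_template
        )
        for seed in (0, 1, 17):
            trace = simulate(models, layout, seed=seed)
            assert np.array_equal(trace.biomass["L"], trace.biomass["S"])

    def test_specialist_pair_coexists_in_two_phases(self, toy3_bundle):
        assignment = dict(toy3_bundle.space.default_config().assignment)
        assignment.update(glc_L=10.0, ac_L=0.0, o2_L=20.0,
                          glc_S=0.0, ac_S=10.0, o2_S=20.0)
        models, layout = apply_config(
            ConsortiumConfig(assignment), toy3_bundle.space,
            toy3_bundle.models, toy3_bundle.layout_template,
        )
        trace = simulate(models, layout, seed=0)
        assert classify_profile(trace) == "coexistence"
        # acetate rises while glucose lasts, then is consumed: two phases
        ac = trace.medium["ac_e"]
        peak = np.argmax(ac)
        assert 0 < peak < len(ac) - 1
        assert ac[-1] < ac[peak]

    def test_space_contains_all_three_fig_profiles(self, toy3_bundle):
        base = dict(toy3_bundle.space.default_config().assignment)
        variants = {
            "coexistence": dict(glc_L=10.0, ac_L=0.0, o2_L=20.0,
                                glc_S=0.0, ac_S=10.0, o2_S=20.0),
            "single_survivor": dict(glc_S=0.0, ac_S=0.0),
            "no_growth": dict(glc_L=0.0, ac_L=0.0, glc_S=0.0, ac_S=0.0),
        }
        for expected, overrides in variants.items():
            models, layout = apply_config(
                ConsortiumConfig({**base, **overrides}), toy3_bundle.space,
                toy3_bundle.models, toy3_bundle.layout_template,
            )
            assert classify_profile(simulate(models, layout, seed=0)) == expected

    def test_five_fitness_goals_score_the_same_trace(self, toy3_bundle):
        assert len(toy3_bundle.fitness_options) == 5
        trace = toy3_bundle.simulate_default(seed=0)
        scores = {
            name: metric_score(trace, spec)
            for name, spec in toy3_bundle.fitness_options.items()
        }
        assert all(np.isfinite(v) for v in scores.values())

    def test_oxygen_stress_forces_more_overflow(self, toy3_bundle):
        base = dict(toy3_bundle.space.default_config().assignment)
        runs = {}
        for o2 in (7.0, 20.0):
            models, layout = apply_config(
                ConsortiumConfig({**base, "o2_L": o2, "o2_S": o2}),
                toy3_bundle.space, toy3_bundle.models, toy3_bundle.layout_template,
            )
            trace = simulate(models, layout, seed=0)
            runs[o2] = np.max(trace.medium["ac_e"])
        assert runs[7.0] > runs[20.0]


class TestRandomCommunity:
    def test_deterministic_construction(self):
        m1, l1 = random_community(5)
        m2, l2 = random_community(5)
        assert m1 == m2
        assert l1.initial_biomass == l2.initial_biomass
        assert l1.medium == l2.medium

    def test_seeds_vary_structure(self):
        sizes = {len(random_community(s)[0]) for s in range(12)}
        assert len(sizes) > 1


class TestRecipes:
    def test_pha_recipe_documents_the_engineering(self):
        recipe = real_case_recipe("pha_consortium")
        text = recipe.describe()
        assert "invertase" in text
        assert "NTRARx" in text and "NTRIR2x" in text
        assert "3.1" in text and "1.83" in text
        assert recipe.required_models == ("iJB785.xml", "iJN1411.xml")

    def test_ltee_recipe_documents_calibration(self):
        recipe = real_case_recipe("ltee")
        text = recipe.describe()
        assert "3.7" in text
        assert "-10" in text or "10 mmol" in text
        assert "iJO1366.xml" in recipe.required_models

    def test_auxotroph_recipe_preserves_reported_discrepancy(self):
        text = real_case_recipe("auxotroph4").describe()
        assert "1.6" in text and "1.5" in text  # both quoted met rates

    def test_unknown_case_rejected(self):
        with pytest.raises(ValueError, match="foo"):
            real_case_recipe("foo")

    def test_refuses_to_run_without_model_files(self, tmp_path):
        recipe = real_case_recipe("pha_consortium")
        with pytest.raises(FileNotFoundError, match="iJB785.xml"):
            recipe.load_models(tmp_path)


class TestCLI:
    def test_fixtures_round_trip(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "fix"
        result = runner.invoke(cli_main, ["fixtures", "toy3", "--out-dir", str(out)])
        assert result.exit_code == 0, result.output
        assert (out / "space.yaml").exists()
        assert (out / "layout.json").exists()
        assert (out / "manifest.json").exists()
        from flexcop import load_space

        assert load_space(out / "space.yaml") == make_overflow_toy().space

    def test_simulate_command(self, tmp_path):
        runner = CliRunner()
        fix = tmp_path / "fix"
        runner.invoke(cli_main, ["fixtures", "toy3", "--out-dir", str(fix)])
        out = tmp_path / "sim"
        result = runner.invoke(cli_main, [
            "simulate", str(fix / "layout.json"),
            str(fix / "L.json"), str(fix / "S.json"),
            "--seed", "1", "--out-dir", str(out),
        ])
        assert result.exit_code == 0, result.output
        assert (out / "trace_wide.csv").exists()
        assert "final biomass" in result.output

    def test_optimize_then_analyze(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "search"
        result = runner.invoke(cli_main, [
            "optimize", "--case", "toy3", "--budget", "6",
            "--replicates", "1", "--seed", "0", "--out-dir", str(out),
        ])
        assert result.exit_code == 0, result.output
        assert "incumbent" in result.output
        result = runner.invoke(cli_main, [
            "analyze", str(out / "history.tsv"),
            "--top-fraction", "0.5", "--out-dir", str(tmp_path / "report"),
        ])
        assert result.exit_code == 0, result.output
        assert (tmp_path / "report" / "correlations.csv").exists()
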