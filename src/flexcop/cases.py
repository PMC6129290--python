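"""Packaged toy consortia.

Three desk-scale case bundles exercise the full design loop end to end,
each emulating a classic consortium-design scenario:

* :func:`make_producer_consumer_toy` — a carbon-fixing producer secreting
  sucrose (a tunable fraction of its fixed carbon) feeding a consumer that
  grows on sucrose + ammonium and accumulates a PHA-like product once
  nitrogen runs out.  Goal: terminal product titre.
* :func:`make_auxotroph_ring_toy` — n amino-acid auxotrophs on a shared
  carbon source, each secreting the next strain's required amino acid at a
  growth-coupled rate.  Goal: parallel growth stability (maximin strain
  growth rate).
* :func:`make_overflow_toy` — two initially identical strains with
  configurable glucose/acetate/oxygen uptake capacities; glucose overflow
  secretes acetate, so glucose-specialist/acetate-specialist polymorphisms
  can emerge.  Goal: selectable among growth rate, biomass, yield and
  time-discounted composites.

Every bundle is built deterministically (no randomness in construction)
and carries machine-checkable ``expected_properties`` run by
``flexcop selftest``.

Stoichiometries use single-digit integer coefficients with carbon
annotations so conservation checks are exact.  The small single-strain
models (:func:`toy_t1`, :func:`toy_t1_with_secretion`,
:func:`toy_phototroph`) are the work-horses of the unit suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .configspace import (
    Binding,
    ConfigSpace,
    ParameterSpec,
    Predicate,
    define_space,
)
from .dfba import CommunityLayout, simulate
from .fitness import CompositeSpec, MetricSpec
from .stoich import Metabolite, Reaction, StoichModel

__all__ = [
    "ToyCaseBundle",
    "toy_t1",
    "toy_t1_with_secretion",
    "toy_phototroph",
    "make_producer_consumer_toy",
    "make_auxotroph_ring_toy",
    "make_overflow_toy",
    "make_case",
    "subspace",
    "CASE_BUILDERS",
]


@dataclass
class ToyCaseBundle:
    """A ready-to-run consortium design problem."""

    name: str
    models: dict[str, StoichModel]
    layout_template: CommunityLayout
    space: ConfigSpace
    fitness: "MetricSpec | CompositeSpec"
    fitness_options: dict[str, "MetricSpec | CompositeSpec"] = field(default_factory=dict)
    expected_properties: list[tuple[str, Callable[["ToyCaseBundle"], None]]] = field(
        default_factory=list
    )

    def simulate_default(self, seed: int = 0):
        from .configspace import apply_config

        config = self.space.default_config()
        models, layout = apply_config(config, self.space, self.models, self.layout_template)
        return simulate(models, layout, seed=seed)

    def selftest(self) -> list[str]:
        """Run the bundle's expected properties; returns their names."""
        passed = []
        for name, check in self.expected_properties:
            check(self)
            passed.append(name)
        return passed


def subspace(space: ConfigSpace, domains: dict[str, tuple[float, ...]]) -> ConfigSpace:
    """Restrict chosen parameters to sub-domains (defaults snap to the
    nearest remaining value); used for small oracle-checkable sweeps."""
    specs = []
    for s in space.specs:
        if s.name in domains:
            dom = tuple(sorted(float(v) for v in domains[s.name]))
            default = min(dom, key=lambda v: abs(v - s.default))
            specs.append(replace(s, domain=dom, default=default))
        else:
            specs.append(s)
    return define_space(specs, space.predicates)


# ---------------------------------------------------------------------------
# small single-strain models
# ---------------------------------------------------------------------------

def toy_t1() -> StoichModel:
    """Minimal heterotroph: glucose uptake (Vmax 10 mmol/gDW/h) feeding a
    growth reaction that consumes 10 mmol glucose per gDW (yield
    0.1 gDW/mmol) and respires 12 C as CO2 out of 60 C taken up."""
    return StoichModel(
        id="T1",
        metabolites=[
            Metabolite("glc_e", "glucose", "external", carbon=6),
            Metabolite("co2_e", "carbon dioxide", "external", carbon=1),
        ],
        reactions=[
            Reaction("EX_glc", {"glc_e": -1}, lb=-10, ub=0, exchange=True),
            Reaction("GROWTH", {"glc_e": -10, "co2_e": 12}, lb=0),
            Reaction("EX_co2", {"co2_e": -1}, lb=0, exchange=True),
        ],
        objective="GROWTH",
        biomass_carbon=48.0,  # 60 C in - 12 C respired per gDW
    )


def toy_t1_with_secretion() -> StoichModel:
    """T1 plus a product-secretion pathway costing 1 glucose per mmol,
    ready for growth-coupling experiments."""
    base = toy_t1()
    return StoichModel(
        id="T1s",
        metabolites=list(base.metabolites)
        + [Metabolite("prod_e", "product", "external", carbon=6)],
        reactions=list(base.reactions)
        + [
            Reaction("SECRETE", {"glc_e": -1, "prod_e": 1}, lb=0),
            Reaction("EX_prod", {"prod_e": -1}, lb=0, exchange=True),
        ],
        objective="GROWTH",
        biomass_carbon=48.0,
    )


def toy_phototroph(fixation_vmax: float = 10.0) -> StoichModel:
    """Carbon fixer: up to ``fixation_vmax`` C-mmol/gDW/h of fixed carbon,
    spendable on growth (10 C per gDW) or sucrose export (12 C per mmol)."""
    return StoichModel(
        id="phototroph",
        metabolites=[
            Metabolite("cfix", "fixed carbon", "internal", carbon=1),
            Metabolite("suc_e", "sucrose", "external", carbon=12),
        ],
        reactions=[
            Reaction("FIX", {"cfix": 1}, lb=0, ub=fixation_vmax),
            Reaction("GROWTH", {"cfix": -10}, lb=0),
            Reaction("SUC_EXPORT", {"cfix": -12, "suc_e": 1}, lb=0),
            Reaction("EX_suc", {"suc_e": -1}, lb=0, exchange=True),
        ],
        objective="GROWTH",
        biomass_carbon=10.0,
    )


# ---------------------------------------------------------------------------
# case 1: producer -> consumer, product under nitrogen limitation
# ---------------------------------------------------------------------------

def _producer_model() -> StoichModel:
    return replace(toy_phototroph(fixation_vmax=0.5), id="synecho")


def _consumer_model() -> StoichModel:
    """Grows on sucrose + ammonium (2 suc + 1 NH4 per gDW); a lexicographic
    second objective maximises product export once growth is fixed, so the
    product flows exactly when nitrogen (not sucrose) is limiting."""
    return StoichModel(
        id="KT",
        metabolites=[
            Metabolite("suc_e", "sucrose", "external", carbon=12),
            Metabolite("nh4_e", "ammonium", "external", carbon=0),
            Metabolite("pha_e", "product", "external", carbon=8),
            Metabolite("co2_e", "carbon dioxide", "external", carbon=1),
        ],
        reactions=[
            Reaction("EX_suc", {"suc_e": -1}, lb=-3.1, ub=0, exchange=True),
            Reaction("EX_nh4", {"nh4_e": -1}, lb=-5, ub=0, exchange=True),
            Reaction("GROWTH", {"suc_e": -2, "nh4_e": -1, "co2_e": 4}, lb=0),
            Reaction("PHA_SYNTH", {"suc_e": -1, "pha_e": 1, "co2_e": 4}, lb=0),
            Reaction("EX_pha", {"pha_e": -1}, lb=0, exchange=True),
            Reaction("EX_co2", {"co2_e": -1}, lb=0, exchange=True),
        ],
        objective="GROWTH",
        secondary_objective="EX_pha",
        biomass_carbon=20.0,
    )


def _check_p_zero_no_product(bundle: ToyCaseBundle) -> None:
    # p = 0 is outside the search domain; check the degenerate coupling directly
    from .stoich import partition_fixed_carbon, solve_fba

    producer = partition_fixed_carbon(bundle.models["synecho"], "FIX", "SUC_EXPORT", 0.0)
    sol = solve_fba(producer)
    assert sol.ok and abs(sol.fluxes["EX_suc"]) < 1e-9, "p=0 must export nothing"


def _check_default_simulates(bundle: ToyCaseBundle) -> None:
    trace = bundle.simulate_default(seed=0)
    assert np.all(trace.total_biomass() >= 0)
    assert all(np.all(c >= 0) for c in trace.medium.values())


def make_producer_consumer_toy(horizon: float = 100.0, dt: float = 0.1) -> ToyCaseBundle:
    """Producer-consumer cross-feeding bundle.

    Tunables: sucrose partition fraction ``sucrPer`` (% of fixed carbon),
    both initial biomasses, and the ammonium pool.  Fitness: product titre
    at the horizon.  An admissibility predicate demands the feeder start
    at least an order of magnitude above the eater.
    """
    models = {"synecho": _producer_model(), "KT": _consumer_model()}
    layout = CommunityLayout(
        initial_biomass={"synecho": 2.0, "KT": 0.1},
        medium={"suc_e": 0.0, "nh4_e": 7.0, "pha_e": 0.0},
        dt=dt,
        horizon=horizon,
    )
    space = define_space(
        [
            ParameterSpec(
                "sucrPer", "cross_feeding_rate",
                domain=(10, 20, 30, 40, 50, 60, 70, 80), default=30,
                binding=Binding(
                    kind="partition_fraction", strain="synecho",
                    reaction="FIX", export_reaction="SUC_EXPORT", scale=0.01,
                ),
            ),
            ParameterSpec(
                "synecho", "strain_ratio", domain=(0.5, 1.0, 1.5, 2.0), default=2.0,
                binding=Binding(kind="initial_biomass", strain="synecho"),
            ),
            ParameterSpec(
                "KT", "strain_ratio", domain=(0.02, 0.05, 0.1, 0.15, 0.2), default=0.1,
                binding=Binding(kind="initial_biomass", strain="KT"),
            ),
            ParameterSpec(
                "NH4", "medium_composition",
                domain=(0.5, 1, 2, 3.5, 5, 7, 10, 15), default=7,
                binding=Binding(kind="medium_pool", metabolite="nh4_e"),
            ),
        ],
        predicates=[
            Predicate(
                name="feeder_ratio", kind="ratio_at_least",
                params=("synecho", "KT"), factor=10.0,
            )
        ],
    )
    fitness = MetricSpec(kind="max_metabolite", target_metabolite="pha_e", horizon=horizon)
    return ToyCaseBundle(
        name="producer_consumer",
        models=models,
        layout_template=layout,
        space=space,
        fitness=fitness,
        expected_properties=[
            ("zero_partition_exports_nothing", _check_p_zero_no_product),
            ("default_config_simulates", _check_default_simulates),
        ],
    )


# ---------------------------------------------------------------------------
# case 2: auxotroph cross-feeding ring
# ---------------------------------------------------------------------------

def _auxotroph_model(i: int, n: int) -> StoichModel:
    aa_in, aa_out = f"aa{i}_e", f"aa{(i % n) + 1}_e"
    return StoichModel(
        id=f"Ec{i}",
        metabolites=[
            Metabolite("glc_e", "glucose", "external", carbon=6),
            Metabolite(aa_in, f"amino acid {i}", "external", carbon=3),
            Metabolite(aa_out, f"amino acid {(i % n) + 1}", "external", carbon=3),
        ],
        reactions=[
            Reaction("EX_glc", {"glc_e": -1}, lb=-10, ub=0, exchange=True),
            Reaction(f"EX_{aa_in}", {aa_in: -1}, lb=-10, ub=0, exchange=True),
            Reaction("GROWTH", {"glc_e": -10, aa_in: -1}, lb=0),
            Reaction("AA_SYNTH", {"glc_e": -1, aa_out: 1}, lb=0),
            Reaction(f"EX_{aa_out}", {aa_out: -1}, lb=0, exchange=True),
        ],
        objective="GROWTH",
    )


def _check_ring_symmetry(bundle: ToyCaseBundle) -> None:
    from .configspace import apply_config
    from .dfba import effective_growth_rate

    config = bundle.space.default_config()
    models, layout = apply_config(config, bundle.space, bundle.models, bundle.layout_template)
    trace = simulate(models, layout, seed=0)
    rates = [effective_growth_rate(trace, s) for s in trace.strains]
    assert max(rates) - min(rates) < 1e-6, "symmetric ring must co-grow equally"


def make_auxotroph_ring_toy(n: int = 4, horizon: float = 10.0, dt: float = 0.1) -> ToyCaseBundle:
    """Ring of ``n`` auxotrophs: strain i requires amino acid i and
    secretes amino acid i+1 growth-coupled at rate ``k_i`` (mmol per unit
    growth; the "% of growth rate" formulation).  Glucose is unlimited;
    each amino acid pool starts with a small 0.05 mM seed so growth can
    bootstrap — with k >= 1 secretion outpaces demand (1 mmol per gDW) and
    the ring sustains itself; with all k = 0 growth stops at the seed.
    """
    if n < 2:
        raise ValueError("a cross-feeding ring needs n >= 2 strains")
    models = {f"Ec{i}": _auxotroph_model(i, n) for i in range(1, n + 1)}
    layout = CommunityLayout(
        initial_biomass={f"Ec{i}": 0.1 for i in range(1, n + 1)},
        medium={f"aa{i}_e": 0.05 for i in range(1, n + 1)},
        dt=dt,
        horizon=horizon,
    )
    specs = []
    for i in range(1, n + 1):
        specs.append(
            ParameterSpec(
                f"Ec{i}", "strain_ratio", domain=(0.05, 0.1, 0.2), default=0.1,
                binding=Binding(kind="initial_biomass", strain=f"Ec{i}"),
            )
        )
    for i in range(1, n + 1):
        specs.append(
            ParameterSpec(
                f"k{i}", "cross_feeding_rate", domain=(0.0, 0.5, 1.0, 1.5, 2.0), default=1.5,
                binding=Binding(kind="coupling_ratio", strain=f"Ec{i}", reaction="AA_SYNTH"),
            )
        )
    space = define_space(specs)
    fitness = MetricSpec(kind="parallel_growth_stability", horizon=horizon)
    return ToyCaseBundle(
        name="auxotroph_ring",
        models=models,
        layout_template=layout,
        space=space,
        fitness=fitness,
        expected_properties=[
            ("symmetric_ring_grows_equally", _check_ring_symmetry),
            ("default_config_simulates", _check_default_simulates),
        ],
    )


# ---------------------------------------------------------------------------
# case 3: overflow-metabolism polymorphism
# ---------------------------------------------------------------------------

def _overflow_model(strain: str) -> StoichModel:
    """Respiration (high yield, O2-hungry), fermentation (low yield,
    secretes acetate) and acetate respiration feed a common biomass
    precursor; carbon is fully accounted (glc 6C -> prec 5C + CO2 etc.)."""
    return StoichModel(
        id=strain,
        metabolites=[
            Metabolite("glc_e", "glucose", "external", carbon=6),
            Metabolite("ac_e", "acetate", "external", carbon=2),
            Metabolite("o2_e", "oxygen", "external", carbon=0),
            Metabolite("co2_e", "carbon dioxide", "external", carbon=1),
            Metabolite("prec", "biomass precursor", "internal", carbon=5),
        ],
        reactions=[
            Reaction("EX_glc", {"glc_e": -1}, lb=-10, ub=0, exchange=True),
            Reaction("EX_ac", {"ac_e": -1}, lb=-10, exchange=True),
            Reaction("EX_o2", {"o2_e": -1}, lb=-20, ub=0, exchange=True),
            Reaction("EX_co2", {"co2_e": -1}, lb=0, exchange=True),
            Reaction("RESP", {"glc_e": -1, "o2_e": -6, "prec": 1, "co2_e": 1}, lb=0),
            Reaction("FERM", {"glc_e": -1, "ac_e": 2, "prec": 0.4}, lb=0),
            Reaction("ACRESP", {"ac_e": -1, "o2_e": -2, "prec": 0.25, "co2_e": 0.75}, lb=0),
            Reaction("GROWTH", {"prec": -10}, lb=0),
        ],
        objective="GROWTH",
        biomass_carbon=50.0,
    )


def _check_identical_strains_identical(bundle: ToyCaseBundle) -> None:
    from .configspace import apply_config

    config = bundle.space.default_config()
    models, layout = apply_config(config, bundle.space, bundle.models, bundle.layout_template)
    trace = simulate(models, layout, seed=3)
    a, b = (trace.biomass[s] for s in trace.strains)
    assert np.array_equal(a, b), "identical strains must trace identically"


def make_overflow_toy(horizon: float = 20.0, dt: float = 0.1) -> ToyCaseBundle:
    """Two initially identical strains (0.01 g/L each) on a finite glucose
    pulse.  The configuration sets each strain's glucose, acetate and
    oxygen uptake capacities; restricted oxygen forces overflow acetate
    secretion, so glucose-specialist / acetate-specialist divisions of
    labour are inside the space.
    """
    models = {"L": _overflow_model("L"), "S": _overflow_model("S")}
    # proportional pool sharing: strains with identical phenotypes must
    # trace identically, so profile classes reflect the configuration,
    # not execution-order luck on the contested glucose pool
    layout = CommunityLayout(
        initial_biomass={"L": 0.01, "S": 0.01},
        medium={"glc_e": 10.0, "ac_e": 0.0, "co2_e": 0.0},
        dt=dt,
        horizon=horizon,
        proportional_split=True,
    )
    specs = []
    for s in ("L", "S"):
        specs += [
            ParameterSpec(
                f"glc_{s}", "co_metabolism", domain=(0.0, 5.0, 10.0), default=10.0,
                binding=Binding(kind="reaction_bound", strain=s, reaction="EX_glc", side="uptake"),
            ),
            ParameterSpec(
                f"ac_{s}", "co_metabolism", domain=(0.0, 5.0, 10.0), default=5.0,
                binding=Binding(kind="reaction_bound", strain=s, reaction="EX_ac", side="uptake"),
            ),
            ParameterSpec(
                f"o2_{s}", "co_metabolism", domain=(7.0, 20.0), default=20.0,
                binding=Binding(kind="reaction_bound", strain=s, reaction="EX_o2", side="uptake"),
            ),
        ]
    space = define_space(specs)
    fitness_options: dict[str, MetricSpec | CompositeSpec] = {
        "max_growth_rate": MetricSpec(kind="max_growth_rate"),
        "max_biomass": MetricSpec(kind="max_biomass"),
        "max_yield": MetricSpec(kind="max_yield", target_metabolite="glc_e"),
        "biomass_min_time": CompositeSpec(
            components=(
                (MetricSpec(kind="max_biomass"), 1.0),
                (MetricSpec(kind="min_time_to_stationary"), 1.0),
            ),
            normalization=(1.0, horizon),
        ),
        "yield_min_time": CompositeSpec(
            components=(
                (MetricSpec(kind="max_yield", target_metabolite="glc_e"), 1.0),
                (MetricSpec(kind="min_time_to_stationary"), 1.0),
            ),
            normalization=(1.0, horizon),
        ),
    }
    return ToyCaseBundle(
        name="overflow_pair",
        models=models,
        layout_template=layout,
        space=space,
        fitness=fitness_options["max_yield"],
        fitness_options=fitness_options,
        expected_properties=[
            ("identical_strains_trace_identically", _check_identical_strains_identical),
            ("default_config_simulates", _check_default_simulates),
        ],
    )


def random_community(
    seed: int | np.random.Generator,
    allow_death: bool = True,
) -> tuple[dict[str, StoichModel], CommunityLayout]:
    """Generate a small randomized community for robustness checks.

    1–3 heterotroph strains with random glucose demand per gDW, random
    uptake Vmax, an optional growth-coupled secretion pathway, a random
    finite glucose pulse and step size.  Fully determined by the seed.
    All models carry consistent carbon annotations, so with
    ``allow_death=False`` the generated layouts conserve carbon exactly.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_strains = int(rng.integers(1, 4))
    models: dict[str, StoichModel] = {}
    medium = {"glc_e": float(rng.uniform(0.5, 20.0)), "co2_e": 0.0, "prod_e": 0.0}
    for i in range(n_strains):
        g = float(rng.uniform(5.0, 20.0))          # glucose per gDW
        co2 = float(rng.uniform(0.0, 0.5)) * 6 * g  # respired carbon share
        vmax = float(rng.uniform(2.0, 15.0))
        mets = [
            Metabolite("glc_e", "glucose", "external", carbon=6),
            Metabolite("co2_e", "carbon dioxide", "external", carbon=1),
            Metabolite("prod_e", "product", "external", carbon=6),
        ]
        rxns = [
            Reaction("EX_glc", {"glc_e": -1}, lb=-vmax, ub=0, exchange=True),
            Reaction("GROWTH", {"glc_e": -g, "co2_e": co2}, lb=0),
            Reaction("EX_co2", {"co2_e": -1}, lb=0, exchange=True),
            Reaction("SECRETE", {"glc_e": -1, "prod_e": 1}, lb=0),
            Reaction("EX_prod", {"prod_e": -1}, lb=0, exchange=True),
        ]
        model = StoichModel(
            id=f"strain{i}",
            metabolites=mets,
            reactions=rxns,
            objective="GROWTH",
            biomass_carbon=6 * g - co2,
        )
        if rng.random() < 0.5:
            from .stoich import add_growth_coupled_secretion

            model = add_growth_coupled_secretion(
                model, "SECRETE", float(rng.uniform(0.0, 2.0))
            )
        models[model.id] = model
    dt = float(rng.choice([0.05, 0.1, 0.25]))
    layout = CommunityLayout(
        initial_biomass={s: float(rng.uniform(0.005, 0.1)) for s in models},
        medium=medium,
        dt=dt,
        horizon=dt * int(rng.integers(10, 31)),
        death_rate=float(rng.choice([0.0, 0.02, 0.05])) if allow_death else 0.0,
    )
    return models, layout


CASE_BUILDERS: dict[str, Callable[[], ToyCaseBundle]] = {
    "toy1": make_producer_consumer_toy,
    "toy2": make_auxotroph_ring_toy,
    "toy3": make_overflow_toy,
}


def make_case(name: str) -> ToyCaseBundle:
    try:
        return CASE_BUILDERS[name]()
    except KeyError:
        raise ValueError(
            f"unknown case {name!r}; available: {sorted(CASE_BUILDERS)}"
        ) from None
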