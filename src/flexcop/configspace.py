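"""Discrete consortium-configuration spaces.

A consortium configuration is one assignment of values to a set of tunable
community parameters: strain ratios (initial biomasses), cross-feeding
rates, medium composition, per-strain uptake capacities, carbon partition
fractions and so on.  Domains are discrete and ordered — the search problem
is a finite grid, which keeps the optimisation tractable and prevents the
search from wasting evaluations on near-identical configurations.

Each parameter carries a declarative *binding* that says what it sets:
an initial biomass, a medium pool, a reaction bound, a growth-coupling
ratio, a carbon partition fraction, or an uptake Vmax.  Bindings are plain
data (never callbacks) so that every evaluated configuration can be
serialised into the run history.

Admissibility *predicates* encode physiological constraints that shrink
the computable space (e.g. "the feeder strain must start at least an order
of magnitude above the eater").  Rejected configurations are never
simulated; they receive the sentinel worst fitness so the search history
stays totally ordered.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import yaml

from .stoich import (
    StoichModel,
    add_growth_coupled_secretion,
    partition_fixed_carbon,
    set_bounds,
)

__all__ = [
    "CATEGORIES",
    "Binding",
    "ParameterSpec",
    "Predicate",
    "ConfigSpace",
    "ConsortiumConfig",
    "Admissibility",
    "ConfigError",
    "BindingError",
    "define_space",
    "apply_config",
    "check_physiology",
    "load_space",
    "save_space",
]

CATEGORIES = (
    "strain_ratio",
    "cross_feeding_rate",
    "co_metabolism",
    "medium_composition",
    "initial_carbon",
    "pathway_fragmentation",
    "aerobic_switch_time",
    "atp_maintenance",
)

BINDING_KINDS = (
    "initial_biomass",     # strain -> X0 (gDW/L)
    "medium_pool",         # metabolite -> concentration (mM)
    "reaction_bound",      # strain.reaction -> lb and/or ub
    "coupling_ratio",      # strain.reaction -> growth-coupled secretion ratio
    "partition_fraction",  # strain.(fixation, export) -> carbon fraction
    "uptake_vmax",         # strain.metabolite -> uptake Vmax (mmol/gDW/h)
    "none",                # free parameter (e.g. purely derived landscapes)
)


class ConfigError(ValueError):
    """Invalid space/configuration definition."""


class BindingError(ConfigError):
    """A binding does not resolve against the models or layout."""


@dataclass(frozen=True)
class Binding:
    """Declarative target of a parameter value.

    ``scale`` multiplies the raw domain value before application, e.g.
    0.01 to express a percentage parameter as a fraction in the model.
    ``side`` selects which bound a ``reaction_bound`` binding sets:
    "lb", "ub", "both" (lb=ub=value) or "uptake" (lb = -value).
    """

    kind: str
    strain: str | None = None
    reaction: str | None = None
    metabolite: str | None = None
    export_reaction: str | None = None
    side: str = "uptake"
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in BINDING_KINDS:
            raise ConfigError(f"unknown binding kind {self.kind!r}")


@dataclass(frozen=True)
class ParameterSpec:
    name: str
    category: str
    domain: tuple[float, ...]
    default: float
    binding: Binding = field(default_factory=lambda: Binding(kind="none"))

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ConfigError(
                f"parameter {self.name!r}: unknown category {self.category!r}"
            )
        dom = tuple(float(v) for v in self.domain)
        if not dom:
            raise ConfigError(f"parameter {self.name!r}: empty domain")
        if any(b <= a for a, b in zip(dom, dom[1:])):
            raise ConfigError(
                f"parameter {self.name!r}: domain must be strictly increasing"
            )
        object.__setattr__(self, "domain", dom)
        object.__setattr__(self, "default", float(self.default))
        if self.default not in dom:
            raise ConfigError(
                f"parameter {self.name!r}: default {self.default} not in domain"
            )


@dataclass(frozen=True)
class Predicate:
    """Named admissibility predicate from the built-in predicate library.

    Kinds:

    * ``ratio_at_least``: value(numerator) >= factor * value(denominator)
    * ``sum_at_most`` / ``sum_at_least``: sum over ``params`` vs ``limit``
    * ``value_at_most`` / ``value_at_least``: single parameter vs ``limit``
    """

    name: str
    kind: str
    params: tuple[str, ...] = ()
    factor: float = 1.0
    limit: float = 0.0

    _KINDS = (
        "ratio_at_least",
        "sum_at_most",
        "sum_at_least",
        "value_at_most",
        "value_at_least",
    )

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ConfigError(f"predicate {self.name!r}: unknown kind {self.kind!r}")
        object.__setattr__(self, "params", tuple(self.params))

    def holds(self, assignment: Mapping[str, float]) -> bool:
        try:
            vals = [assignment[p] for p in self.params]
        except KeyError as exc:
            raise ConfigError(
                f"predicate {self.name!r} references unknown parameter {exc}"
            ) from exc
        if self.kind == "ratio_at_least":
            num, den = vals
            return num >= self.factor * den
        if self.kind == "sum_at_most":
            return sum(vals) <= self.limit
        if self.kind == "sum_at_least":
            return sum(vals) >= self.limit
        if self.kind == "value_at_most":
            return vals[0] <= self.limit
        return vals[0] >= self.limit


@dataclass(frozen=True)
class ConsortiumConfig:
    """One complete, in-domain assignment over a space's parameters."""

    assignment: Mapping[str, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "assignment", dict(self.assignment))

    def __getitem__(self, name: str) -> float:
        return self.assignment[name]

    def key(self) -> tuple[tuple[str, float], ...]:
        return tuple(sorted(self.assignment.items()))

    def __hash__(self) -> int:
        return hash(self.key())

    def __eq__(self, other) -> bool:
        return isinstance(other, ConsortiumConfig) and self.key() == other.key()


@dataclass(frozen=True)
class Admissibility:
    admissible: bool
    reason: str | None = None


@dataclass(frozen=True)
class ConfigSpace:
    specs: tuple[ParameterSpec, ...]
    predicates: tuple[Predicate, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "specs", tuple(self.specs))
        object.__setattr__(self, "predicates", tuple(self.predicates))

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.specs]

    def spec(self, name: str) -> ParameterSpec:
        for s in self.specs:
            if s.name == name:
                return s
        raise KeyError(f"no parameter named {name!r}")

    def size(self) -> int:
        n = 1
        for s in self.specs:
            n *= len(s.domain)
        return n

    def default_config(self) -> ConsortiumConfig:
        return ConsortiumConfig({s.name: s.default for s in self.specs})

    def validate_config(self, config: ConsortiumConfig) -> None:
        missing = [s.name for s in self.specs if s.name not in config.assignment]
        if missing:
            raise ConfigError(f"configuration missing parameters: {missing}")
        extra = set(config.assignment) - set(self.names)
        if extra:
            raise ConfigError(f"configuration has unknown parameters: {sorted(extra)}")
        for s in self.specs:
            if config[s.name] not in s.domain:
                raise ConfigError(
                    f"value {config[s.name]} for parameter {s.name!r} is not "
                    f"in its domain {s.domain}"
                )

    def enumerate(self) -> Iterator[ConsortiumConfig]:
        """All configurations in lexicographic order of the spec order."""

        def rec(i: int, acc: dict[str, float]) -> Iterator[ConsortiumConfig]:
            if i == len(self.specs):
                yield ConsortiumConfig(dict(acc))
                return
            s = self.specs[i]
            for v in s.domain:
                acc[s.name] = v
                yield from rec(i + 1, acc)
            del acc[s.name]

        yield from rec(0, {})

    def encode(self, config: ConsortiumConfig) -> list[int]:
        """Ordinal encoding (index within each domain), in spec order."""
        return [s.domain.index(config[s.name]) for s in self.specs]


def define_space(
    specs: Sequence[ParameterSpec], predicates: Sequence[Predicate] = ()
) -> ConfigSpace:
    """Validate and build a configuration space."""
    if not specs:
        raise ConfigError("a configuration space needs at least one parameter")
    names = [s.name for s in specs]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise ConfigError(f"duplicate parameter names: {sorted(dupes)}")
    return ConfigSpace(specs=tuple(specs), predicates=tuple(predicates))


def check_physiology(
    config: ConsortiumConfig, predicates: Sequence[Predicate]
) -> Admissibility:
    """Evaluate admissibility predicates in order; first failure wins."""
    for pred in predicates:
        if not pred.holds(config.assignment):
            return Admissibility(False, reason=pred.name)
    return Admissibility(True)


# ---------------------------------------------------------------------------
# applying a configuration
# ---------------------------------------------------------------------------

def _apply_binding(
    binding: Binding,
    value: float,
    models: dict[str, StoichModel],
    layout,
) -> None:
    """Apply one bound parameter value in place on working copies."""
    v = value * binding.scale
    kind = binding.kind
    if kind == "none":
        return
    if kind == "initial_biomass":
        if binding.strain not in layout.initial_biomass:
            raise BindingError(
                f"initial_biomass binding targets unknown strain {binding.strain!r}"
            )
        layout.initial_biomass[binding.strain] = v
        return
    if kind == "medium_pool":
        layout.medium[binding.metabolite] = v
        return
    if kind == "uptake_vmax":
        if binding.strain not in layout.initial_biomass:
            raise BindingError(
                f"uptake_vmax binding targets unknown strain {binding.strain!r}"
            )
        layout.set_uptake(binding.strain, binding.metabolite, vmax=v)
        return
    # remaining kinds mutate a strain model
    if binding.strain not in models:
        raise BindingError(f"binding targets unknown strain {binding.strain!r}")
    model = models[binding.strain]
    try:
        if kind == "reaction_bound":
            rxn = model.reaction(binding.reaction)
            if binding.side == "lb":
                models[binding.strain] = set_bounds(model, binding.reaction, v, rxn.ub)
            elif binding.side == "ub":
                models[binding.strain] = set_bounds(model, binding.reaction, rxn.lb, v)
            elif binding.side == "both":
                models[binding.strain] = set_bounds(model, binding.reaction, v, v)
            elif binding.side == "uptake":
                models[binding.strain] = set_bounds(model, binding.reaction, -v, rxn.ub)
            else:
                raise ConfigError(f"unknown bound side {binding.side!r}")
        elif kind == "coupling_ratio":
            models[binding.strain] = add_growth_coupled_secretion(
                model, binding.reaction, v
            )
        elif kind == "partition_fraction":
            models[binding.strain] = partition_fixed_carbon(
                model, binding.reaction, binding.export_reaction, v
            )
    except KeyError as exc:
        raise BindingError(f"binding does not resolve: {exc}") from exc


def apply_config(
    config: ConsortiumConfig,
    space: ConfigSpace,
    base_models: Mapping[str, StoichModel],
    layout_template,
):
    """Instantiate a configuration: returns ``(models, layout)`` ready to
    simulate.

    Pure function of its inputs: the base models and the layout template
    are never mutated; bindings are applied in spec order.
    """
    space.validate_config(config)
    models = dict(base_models)
    layout = layout_template.copy()
    for spec in space.specs:
        _apply_binding(spec.binding, config[spec.name], models, layout)
    return models, layout


# ---------------------------------------------------------------------------
# space (de)serialisation — YAML/JSON, lossless round trip
# ---------------------------------------------------------------------------

def space_to_dict(space: ConfigSpace) -> dict:
    return {
        "parameters": [
            {
                "name": s.name,
                "category": s.category,
                "domain": list(s.domain),
                "default": s.default,
                "binding": {
                    k: v
                    for k, v in {
                        "kind": s.binding.kind,
                        "strain": s.binding.strain,
                        "reaction": s.binding.reaction,
                        "metabolite": s.binding.metabolite,
                        "export_reaction": s.binding.export_reaction,
                        "side": s.binding.side,
                        "scale": s.binding.scale,
                    }.items()
                    if v is not None
                },
            }
            for s in space.specs
        ],
        "predicates": [
            {
                "name": p.name,
                "kind": p.kind,
                "params": list(p.params),
                "factor": p.factor,
                "limit": p.limit,
            }
            for p in space.predicates
        ],
    }


def space_from_dict(doc: Mapping) -> ConfigSpace:
    specs = []
    for s in doc["parameters"]:
        b = s.get("binding", {"kind": "none"})
        specs.append(
            ParameterSpec(
                name=s["name"],
                category=s["category"],
                domain=tuple(s["domain"]),
                default=s["default"],
                binding=Binding(
                    kind=b.get("kind", "none"),
                    strain=b.get("strain"),
                    reaction=b.get("reaction"),
                    metabolite=b.get("metabolite"),
                    export_reaction=b.get("export_reaction"),
                    side=b.get("side", "uptake"),
                    scale=b.get("scale", 1.0),
                ),
            )
        )
    predicates = [
        Predicate(
            name=p["name"],
            kind=p["kind"],
            params=tuple(p.get("params", ())),
            factor=p.get("factor", 1.0),
            limit=p.get("limit", 0.0),
        )
        for p in doc.get("predicates", [])
    ]
    return define_space(specs, predicates)


def save_space(space: ConfigSpace, path: str | Path) -> None:
    path = Path(path)
    doc = space_to_dict(space)
    if path.suffix in (".yml", ".yaml"):
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
    else:
        path.write_text(json.dumps(doc, indent=2) + "\n")


def load_space(path: str | Path) -> ConfigSpace:
    path = Path(path)
    text = path.read_text()
    doc = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
    return space_from_dict(doc)
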