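"""Stoichiometric models and flux balance analysis.

The model type here is deliberately small: metabolites, reactions with
bounds, an objective reaction, and optional *flux couplings* — exact linear
equalities ``v_target = k * v_source`` added to the LP.  Couplings are the
mechanism behind growth-coupled secretion ("secrete metabolite M at k units
per unit of growth") and carbon partitioning ("dedicate fraction p of fixed
carbon to an export product"), the two model mutations a consortium designer
applies most often.

Conventions (fixed across the package):

* fluxes in mmol gDW^-1 h^-1, the biomass/objective reaction in h^-1;
* uptake is a *negative* exchange flux (BiGG convention);
* exchange reactions touch exactly one external metabolite.

FBA is solved with scipy's HiGHS backend.  Objective values are unique;
flux vectors at degenerate optima are not — ``solve_fba`` reports the
solver's vertex, with an optional parsimonious second stage (minimise
total absolute flux at the fixed optimum) for reproducible flux vectors.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy.optimize import linprog

logger = logging.getLogger(__name__)

__all__ = [
    "Metabolite",
    "Reaction",
    "FluxCoupling",
    "StoichModel",
    "FluxSolution",
    "ModelSchemaError",
    "read_model",
    "write_model",
    "solve_fba",
    "set_bounds",
    "add_growth_coupled_secretion",
    "partition_fixed_carbon",
]

#: numerical tolerance used when checking S.v = 0 on reported optima
MASS_BALANCE_TOL = 1e-6


class ModelSchemaError(ValueError):
    """A model document or model mutation violates the schema."""


@dataclass(frozen=True)
class Metabolite:
    """A chemical species; ``external`` species are the only ones that can
    be exchanged with the shared medium."""

    id: str
    name: str = ""
    compartment: str = "internal"  # {"internal", "external"}
    carbon: int | None = None  # carbon atoms per molecule, for balance checks

    def __post_init__(self) -> None:
        if self.compartment not in ("internal", "external"):
            raise ModelSchemaError(
                f"metabolite {self.id!r}: compartment must be "
                f"'internal' or 'external', got {self.compartment!r}"
            )
        if self.carbon is not None and self.carbon < 0:
            raise ModelSchemaError(f"metabolite {self.id!r}: negative carbon count")


@dataclass(frozen=True)
class Reaction:
    """A stoichiometric reaction with flux bounds.

    ``stoich`` maps metabolite id to signed coefficient (negative =
    consumed).  ``exchange`` marks boundary reactions: they touch exactly
    one external metabolite and a negative flux means uptake from the
    medium.
    """

    id: str
    stoich: Mapping[str, float]
    lb: float = 0.0
    ub: float = math.inf
    exchange: bool = False

    def __post_init__(self) -> None:
        if self.lb > self.ub:
            raise ModelSchemaError(
                f"reaction {self.id!r}: lb {self.lb} > ub {self.ub}"
            )
        object.__setattr__(self, "stoich", dict(self.stoich))


@dataclass(frozen=True)
class FluxCoupling:
    """Exact linear equality ``v_target = ratio * v_source`` in the LP."""

    source: str
    target: str
    ratio: float


@dataclass(frozen=True)
class FluxSolution:
    status: str  # {"optimal", "infeasible", "unbounded"}
    objective_value: float | None
    fluxes: dict[str, float] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


@dataclass(frozen=True)
class StoichModel:
    """A validated stoichiometric network.

    ``biomass_carbon`` (C-mmol per gDW) lets the dynamic simulator do exact
    carbon book-keeping on annotated toy models; it is optional and ignored
    by FBA itself.  ``secondary_objective`` names a reaction maximised
    lexicographically after the primary objective (e.g. product formation
    once growth is fixed at its optimum).
    """

    metabolites: tuple[Metabolite, ...]
    reactions: tuple[Reaction, ...]
    objective: str
    couplings: tuple[FluxCoupling, ...] = ()
    secondary_objective: str | None = None
    biomass_carbon: float | None = None
    id: str = "model"

    def __post_init__(self) -> None:
        object.__setattr__(self, "metabolites", tuple(self.metabolites))
        object.__setattr__(self, "reactions", tuple(self.reactions))
        object.__setattr__(self, "couplings", tuple(self.couplings))
        self._validate()

    # -- validation -----------------------------------------------------
    def _validate(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            raise ModelSchemaError(f"model {self.id!r}: duplicate metabolite ids")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            raise ModelSchemaError(f"model {self.id!r}: duplicate reaction ids")
        mets = {m.id: m for m in self.metabolites}
        for rxn in self.reactions:
            for mid in rxn.stoich:
                if mid not in mets:
                    raise ModelSchemaError(
                        f"reaction {rxn.id!r} references undeclared metabolite {mid!r}"
                    )
            if rxn.exchange:
                ext = [m for m in rxn.stoich if mets[m].compartment == "external"]
                if len(rxn.stoich) != 1 or len(ext) != 1:
                    raise ModelSchemaError(
                        f"exchange reaction {rxn.id!r} must touch exactly one "
                        "external metabolite"
                    )
        if self.objective not in set(rxn_ids):
            raise ModelSchemaError(
                f"model {self.id!r}: objective reaction {self.objective!r} missing"
            )
        if self.secondary_objective is not None and self.secondary_objective not in set(rxn_ids):
            raise ModelSchemaError(
                f"model {self.id!r}: secondary objective "
                f"{self.secondary_objective!r} missing"
            )
        for c in self.couplings:
            for rid in (c.source, c.target):
                if rid not in set(rxn_ids):
                    raise ModelSchemaError(
                        f"coupling references unknown reaction {rid!r}"
                    )

    # -- lookups --------------------------------------------------------
    @property
    def metabolite_map(self) -> dict[str, Metabolite]:
        return {m.id: m for m in self.metabolites}

    @property
    def reaction_map(self) -> dict[str, Reaction]:
        return {r.id: r for r in self.reactions}

    def reaction(self, rid: str) -> Reaction:
        try:
            return self.reaction_map[rid]
        except KeyError:
            raise KeyError(f"model {self.id!r} has no reaction {rid!r}") from None

    def exchange_reactions(self) -> list[tuple[Reaction, Metabolite]]:
        """Exchange reactions paired with their external metabolite."""
        mets = self.metabolite_map
        out = []
        for r in self.reactions:
            if r.exchange:
                (mid,) = r.stoich.keys()
                out.append((r, mets[mid]))
        return out

    def stoichiometric_matrix(self) -> tuple[np.ndarray, list[str], list[str]]:
        """Dense S matrix plus row (metabolite) and column (reaction) ids."""
        met_ids = [m.id for m in self.metabolites]
        rxn_ids = [r.id for r in self.reactions]
        midx = {m: i for i, m in enumerate(met_ids)}
        S = np.zeros((len(met_ids), len(rxn_ids)))
        for j, r in enumerate(self.reactions):
            for mid, coef in r.stoich.items():
                S[midx[mid], j] = coef
        return S, met_ids, rxn_ids


# ---------------------------------------------------------------------------
# model document I/O
# ---------------------------------------------------------------------------

def _model_to_dict(model: StoichModel) -> dict:
    doc: dict = {
        "id": model.id,
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                **({"carbon": m.carbon} if m.carbon is not None else {}),
            }
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "stoich": dict(r.stoich),
                "lb": None if r.lb == -math.inf else r.lb,
                "ub": None if r.ub == math.inf else r.ub,
                "exchange": r.exchange,
            }
            for r in model.reactions
        ],
        "couplings": [
            {"source": c.source, "target": c.target, "ratio": c.ratio}
            for c in model.couplings
        ],
        "objective": model.objective,
    }
    if model.secondary_objective is not None:
        doc["secondary_objective"] = model.secondary_objective
    if model.biomass_carbon is not None:
        doc["biomass_carbon"] = model.biomass_carbon
    return doc


def _model_from_dict(doc: Mapping) -> StoichModel:
    try:
        mets = [
            Metabolite(
                id=m["id"],
                name=m.get("name", ""),
                compartment=m.get("compartment", "internal"),
                carbon=m.get("carbon"),
            )
            for m in doc["metabolites"]
        ]
        rxns = [
            Reaction(
                id=r["id"],
                stoich=r["stoich"],
                lb=-math.inf if r.get("lb") is None else float(r["lb"]),
                ub=math.inf if r.get("ub") is None else float(r["ub"]),
                exchange=bool(r.get("exchange", False)),
            )
            for r in doc["reactions"]
        ]
        couplings = [
            FluxCoupling(c["source"], c["target"], float(c["ratio"]))
            for c in doc.get("couplings", [])
        ]
        objective = doc["objective"]
    except KeyError as exc:
        raise ModelSchemaError(f"model document missing field: {exc}") from exc
    return StoichModel(
        metabolites=mets,
        reactions=rxns,
        objective=objective,
        couplings=couplings,
        secondary_objective=doc.get("secondary_objective"),
        biomass_carbon=doc.get("biomass_carbon"),
        id=doc.get("id", "model"),
    )


def _read_sbml_fbc(path: str | Path) -> StoichModel:
    """Import an SBML Level-3 FBC document via cobrapy.

    Only stoichiometry, FBC bounds and the FBC objective are mapped;
    kinetic laws and GPR rules are ignored (with a log message).
    """
    import cobra.io

    cmodel = cobra.io.read_sbml_model(str(path))
    logger.warning(
        "SBML import of %s: only stoichiometry, FBC bounds and objective are "
        "used; kinetic laws and gene rules are ignored",
        path,
    )
    boundary = {r.id for r in cmodel.boundary}
    # external = species touched by a boundary reaction
    external = set()
    for r in cmodel.boundary:
        external.update(m.id for m in r.metabolites)
    mets = [
        Metabolite(
            id=m.id,
            name=m.name or "",
            compartment="external" if m.id in external else "internal",
        )
        for m in cmodel.metabolites
    ]
    rxns = [
        Reaction(
            id=r.id,
            stoich={m.id: coef for m, coef in r.metabolites.items()},
            lb=r.lower_bound,
            ub=r.upper_bound,
            exchange=r.id in boundary,
        )
        for r in cmodel.reactions
    ]
    objective_rxns = [
        r.id for r in cmodel.reactions if r.objective_coefficient != 0
    ]
    if not objective_rxns:
        raise ModelSchemaError(f"SBML model {path} declares no FBC objective")
    return StoichModel(
        metabolites=mets,
        reactions=rxns,
        objective=objective_rxns[0],
        id=cmodel.id or "sbml_model",
    )


def read_model(document: str | Path | Mapping, dialect: str = "native-json") -> StoichModel:
    """Read a model from a document.

    Parameters
    ----------
    document:
        A path, a JSON string, or an already-parsed mapping (native dialect
        only; SBML requires a path).
    dialect:
        ``"native-json"`` or ``"sbml-fbc"``.
    """
    if dialect == "sbml-fbc":
        return _read_sbml_fbc(document)  # type: ignore[arg-type]
    if dialect != "native-json":
        raise ValueError(f"unknown model dialect {dialect!r}")
    if isinstance(document, Mapping):
        return _model_from_dict(document)
    text = None
    p = Path(str(document))
    try:
        if p.exists():
            text = p.read_text()
    except OSError:
        pass
    if text is None:
        text = str(document)
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ModelSchemaError(f"model document is not valid JSON: {exc}") from exc
    return _model_from_dict(doc)


def write_model(model: StoichModel, path: str | Path | None = None) -> str:
    """Serialise to the native JSON dialect; returns the JSON text."""
    text = json.dumps(_model_to_dict(model), indent=2, sort_keys=False)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


# ---------------------------------------------------------------------------
# model mutation
# ---------------------------------------------------------------------------

def set_bounds(model: StoichModel, reaction_id: str, lb: float, ub: float) -> StoichModel:
    """Return a copy of ``model`` with the bounds of one reaction replaced."""
    if lb > ub:
        raise ValueError(f"lb {lb} > ub {ub} for reaction {reaction_id!r}")
    model.reaction(reaction_id)  # raises KeyError if unknown
    new_rxns = tuple(
        replace(r, lb=float(lb), ub=float(ub)) if r.id == reaction_id else r
        for r in model.reactions
    )
    return replace(model, reactions=new_rxns)


def add_growth_coupled_secretion(
    model: StoichModel, secretion_reaction: str, k: float
) -> StoichModel:
    """Couple a secretion flux to growth: ``v_secretion = k * mu``.

    ``k`` is the secretion rate expressed per unit of growth rate (the
    "percentage of GR" formulation divided by 100 when quoted as a
    percentage).
    """
    if k < 0:
        raise ValueError(f"coupling ratio k must be >= 0, got {k}")
    model.reaction(secretion_reaction)  # raises on unknown id
    coupling = FluxCoupling(source=model.objective, target=secretion_reaction, ratio=float(k))
    return replace(model, couplings=model.couplings + (coupling,))


def _carbon_throughput(model: StoichModel, reaction_id: str) -> float:
    """Carbon atoms produced per unit flux of a reaction (sum over products)."""
    mets = model.metabolite_map
    rxn = model.reaction(reaction_id)
    total = 0.0
    for mid, coef in rxn.stoich.items():
        if coef > 0:
            carbon = mets[mid].carbon
            if carbon is None:
                raise ModelSchemaError(
                    f"metabolite {mid!r} in reaction {reaction_id!r} lacks a "
                    "carbon annotation required for carbon partitioning"
                )
            total += coef * carbon
    return total


def partition_fixed_carbon(
    model: StoichModel, fixation_reaction: str, export_reaction: str, p: float
) -> StoichModel:
    """Dedicate fraction ``p`` of fixed carbon to an export product.

    Adds the coupling row ``c_e * v_export = p * c_f * v_fix`` where ``c_f``
    and ``c_e`` are the carbon throughputs (C-atoms per unit flux) of the
    fixation and export reactions.  ``p`` must lie in [0, 1): partitioning
    every fixed carbon atom to export leaves none for growth and is
    rejected.
    """
    if not (0.0 <= p < 1.0):
        raise ValueError(f"partition fraction p must be in [0, 1), got {p}")
    c_fix = _carbon_throughput(model, fixation_reaction)
    c_exp = _carbon_throughput(model, export_reaction)
    if c_fix <= 0 or c_exp <= 0:
        raise ModelSchemaError(
            "fixation and export reactions must both produce carbon "
            f"(got {c_fix} and {c_exp} C per unit flux)"
        )
    ratio = p * c_fix / c_exp
    coupling = FluxCoupling(source=fixation_reaction, target=export_reaction, ratio=ratio)
    return replace(model, couplings=model.couplings + (coupling,))


# ---------------------------------------------------------------------------
# FBA
# ---------------------------------------------------------------------------

import weakref

# identity-keyed cache (models hold dicts, so they are not hashable);
# a weakref finalizer evicts entries when the model is collected
_LP_CACHE: dict[int, tuple] = {}


def _lp_base(model: StoichModel) -> tuple[np.ndarray, np.ndarray, list, list[str]]:
    """Equality system and base bounds, cached per model instance."""
    key = id(model)
    entry = _LP_CACHE.get(key)
    if entry is not None and entry[0]() is model:
        return entry[1]
    S, _met_ids, rxn_ids = model.stoichiometric_matrix()
    ridx = {r: j for j, r in enumerate(rxn_ids)}
    rows = [S]
    for c in model.couplings:
        row = np.zeros(len(rxn_ids))
        row[ridx[c.target]] = 1.0
        row[ridx[c.source]] = -c.ratio
        rows.append(row[None, :])
    A_eq = np.vstack(rows)
    b_eq = np.zeros(A_eq.shape[0])
    base_bounds = [
        (None if r.lb == -math.inf else r.lb, None if r.ub == math.inf else r.ub)
        for r in model.reactions
    ]
    result = (A_eq, b_eq, base_bounds, rxn_ids)
    _LP_CACHE[key] = (
        weakref.ref(model, lambda _r, k=key: _LP_CACHE.pop(k, None)),
        result,
    )
    return result


def _lp_arrays(
    model: StoichModel, bound_overrides: Mapping[str, tuple[float, float]] | None
) -> tuple[np.ndarray, np.ndarray, list[tuple[float, float]], list[str]]:
    A_eq, b_eq, base_bounds, rxn_ids = _lp_base(model)
    if not bound_overrides:
        return A_eq, b_eq, base_bounds, rxn_ids
    bounds = list(base_bounds)
    ridx = {r: j for j, r in enumerate(rxn_ids)}
    for rid, (lb, ub) in bound_overrides.items():
        bounds[ridx[rid]] = (
            None if lb == -math.inf else lb,
            None if ub == math.inf else ub,
        )
    return A_eq, b_eq, bounds, rxn_ids


def solve_fba(
    model: StoichModel,
    sense: str = "maximize",
    bound_overrides: Mapping[str, tuple[float, float]] | None = None,
    parsimonious: bool = False,
) -> FluxSolution:
    """Solve the flux balance LP: optimise the objective flux subject to
    ``S.v = 0``, coupling equalities and flux bounds.

    Infeasible and unbounded problems are reported through
    ``FluxSolution.status``, never raised.  When the model declares a
    ``secondary_objective``, a lexicographic second solve maximises it with
    the primary objective fixed at its optimum (the reported
    ``objective_value`` stays the primary optimum).  ``parsimonious``
    requests a final stage minimising total absolute flux at the fixed
    optimum, for a reproducible flux vector on degenerate LPs.
    """
    if sense not in ("maximize", "minimize"):
        raise ValueError(f"sense must be 'maximize' or 'minimize', got {sense!r}")
    A_eq, b_eq, bounds, rxn_ids = _lp_arrays(model, bound_overrides)
    n = len(rxn_ids)
    ridx = {r: j for j, r in enumerate(rxn_ids)}
    c = np.zeros(n)
    c[ridx[model.objective]] = -1.0 if sense == "maximize" else 1.0

    res = linprog(c, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
    if res.status == 2:
        return FluxSolution(status="infeasible", objective_value=None)
    if res.status == 3:
        return FluxSolution(status="unbounded", objective_value=None)
    if not res.success:  # numerical trouble: report as infeasible
        return FluxSolution(status="infeasible", objective_value=None)
    obj = float(res.x[ridx[model.objective]])
    x = res.x

    def _resolve(extra_c: np.ndarray, fix_rows: list[tuple[np.ndarray, float]]):
        A2 = np.vstack([A_eq] + [r[None, :] for r, _ in fix_rows])
        b2 = np.concatenate([b_eq, [v for _, v in fix_rows]])
        return linprog(extra_c, A_eq=A2, b_eq=b2, bounds=bounds, method="highs")

    fix_primary = np.zeros(n)
    fix_primary[ridx[model.objective]] = 1.0
    fixes = [(fix_primary, obj)]

    if model.secondary_objective is not None:
        c2 = np.zeros(n)
        c2[ridx[model.secondary_objective]] = -1.0  # secondary is maximised
        res2 = _resolve(c2, fixes)
        if res2.success:
            x = res2.x
            fix_secondary = np.zeros(n)
            fix_secondary[ridx[model.secondary_objective]] = 1.0
            fixes.append((fix_secondary, float(x[ridx[model.secondary_objective]])))

    if parsimonious:
        # min sum |v| at the fixed optimum, via v = v+ - v- splitting
        A2 = np.vstack([A_eq] + [r[None, :] for r, _ in fixes])
        b2 = np.concatenate([b_eq, [v for _, v in fixes]])
        Asplit = np.hstack([A2, -A2])
        csplit = np.ones(2 * n)
        bsplit = []
        for lo, hi in bounds:
            bsplit.append((0, None if hi is None else max(hi, 0)))
        for lo, hi in bounds:
            bsplit.append((0, None if lo is None else max(-lo, 0)))
        res3 = linprog(csplit, A_eq=Asplit, b_eq=b2, bounds=bsplit, method="highs")
        if res3.success:
            x = res3.x[:n] - res3.x[n:]

    fluxes = {rid: float(v) for rid, v in zip(rxn_ids, x)}
    return FluxSolution(status="optimal", objective_value=obj, fluxes=fluxes)
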