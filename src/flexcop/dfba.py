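"""Dynamic FBA of a well-mixed community in a single compartment.

The simulator advances a shared metabolite medium and per-strain biomasses
on a fixed Euler grid.  At every step the strain order is randomly permuted
(seeded); each strain in turn gets its exchange uptake bounds set from the
*current* — already partially depleted — pools, its FBA problem is solved,
and the pools are debited/credited immediately.  This sequential sharing is
the source of replicate-to-replicate variability: replicate runs of the
same configuration differ only in the order strains draw on the shared
pools.  Secreted products accumulate in the medium and are re-consumable
by any strain that can take them up — metabolite accumulation is a
first-class part of the dynamics, not an assumed instantaneous transfer.

Per step, for strain i with biomass X_i and realized growth rate mu_i:

    X_i <- X_i * (1 + (mu_i - delta) * dt)        (delta = death rate)
    pool_m <- pool_m + v_{i,m} * X_i * dt          (mM; clamped at 0)

The uptake bound for a finite pool at concentration c is

    min(Vmax * c/(Km+c) if Km else Vmax,  c / (X * dt))

i.e. Michaelis-Menten saturation when kinetics are given, and never more
than what the pool can physically supply within the step.  Metabolites not
listed in the medium are treated as unlimited (minimal-medium convention:
water, ions, CO2 are not tracked).

A per-step infeasible FBA is not fatal: the strain simply does not grow
that step (mu = 0, flagged), which is the physiological reading of an
unsatisfiable steady-state demand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .stoich import FluxSolution, StoichModel, solve_fba

__all__ = [
    "UptakeSpec",
    "SerialTransfer",
    "CommunityLayout",
    "SimulationTrace",
    "LayoutError",
    "uptake_bound",
    "simulate",
    "effective_growth_rate",
]

#: concentrations below this are clamped to zero after each step
POOL_CLAMP_TOL = 1e-12


class LayoutError(ValueError):
    """Invalid community layout."""


@dataclass(frozen=True)
class UptakeSpec:
    """Uptake capacity of one strain for one medium metabolite.

    ``vmax`` in mmol gDW^-1 h^-1; ``km`` (mM) is optional — when absent no
    saturation kinetics are applied.
    """

    strain: str
    metabolite: str
    vmax: float
    km: float | None = None

    def __post_init__(self) -> None:
        if self.vmax < 0:
            raise LayoutError(f"uptake Vmax must be >= 0, got {self.vmax}")
        if self.km is not None and self.km <= 0:
            raise LayoutError(f"uptake Km must be > 0 when given, got {self.km}")


@dataclass(frozen=True)
class SerialTransfer:
    """Optional serial-transfer regime: every ``interval`` hours the culture
    is diluted by ``dilution`` and finite pools are reset to their initial
    concentrations (fresh medium)."""

    interval: float
    dilution: float

    def __post_init__(self) -> None:
        if self.interval <= 0 or not (0 < self.dilution <= 1):
            raise LayoutError("serial transfer needs interval > 0 and 0 < dilution <= 1")


@dataclass
class CommunityLayout:
    """Strains with initial biomasses, shared finite pools and step control.

    ``initial_biomass``: strain id -> X0 (gDW/L).  ``medium``: external
    metabolite id -> concentration (mM); metabolites absent from the map
    are unlimited.  ``dt`` and ``horizon`` in hours; ``death_rate`` in h^-1.
    """

    initial_biomass: dict[str, float]
    medium: dict[str, float]
    uptake_specs: list[UptakeSpec] = field(default_factory=list)
    dt: float = 0.1
    horizon: float = 100.0
    death_rate: float = 0.0
    serial_transfer: SerialTransfer | None = None
    proportional_split: bool = False  # alternative pool-sharing rule

    def __post_init__(self) -> None:
        if not self.initial_biomass:
            raise LayoutError("layout declares no strains")
        if any(x < 0 for x in self.initial_biomass.values()):
            raise LayoutError("initial biomasses must be >= 0")
        if any(c < 0 for c in self.medium.values()):
            raise LayoutError("medium concentrations must be >= 0")
        if not (0 < self.dt <= self.horizon):
            raise LayoutError(f"need 0 < dt <= horizon, got dt={self.dt}, horizon={self.horizon}")
        if self.death_rate < 0:
            raise LayoutError("death rate must be >= 0")

    def copy(self) -> "CommunityLayout":
        return CommunityLayout(
            initial_biomass=dict(self.initial_biomass),
            medium=dict(self.medium),
            uptake_specs=list(self.uptake_specs),
            dt=self.dt,
            horizon=self.horizon,
            death_rate=self.death_rate,
            serial_transfer=self.serial_transfer,
            proportional_split=self.proportional_split,
        )

    def set_uptake(self, strain: str, metabolite: str, vmax: float, km: float | None = None) -> None:
        self.uptake_specs = [
            u for u in self.uptake_specs
            if not (u.strain == strain and u.metabolite == metabolite)
        ]
        self.uptake_specs.append(UptakeSpec(strain, metabolite, vmax, km))

    def uptake_spec(self, strain: str, metabolite: str) -> UptakeSpec | None:
        for u in self.uptake_specs:
            if u.strain == strain and u.metabolite == metabolite:
                return u
        return None


@dataclass(frozen=True)
class SimulationTrace:
    """Time series output of one community simulation.

    ``times`` has ``n_steps + 1`` points (0 .. horizon); biomass and medium
    series align with it.  ``mu`` and ``status`` are per-step (length
    ``n_steps``): ``mu[s][k]`` is the growth rate realized on the step from
    ``times[k]`` to ``times[k+1]``.
    """

    times: np.ndarray
    biomass: dict[str, np.ndarray]
    medium: dict[str, np.ndarray]
    mu: dict[str, np.ndarray]
    status: dict[str, list[str]]
    meta: dict = field(default_factory=dict)

    @property
    def strains(self) -> list[str]:
        return list(self.biomass)

    @property
    def horizon(self) -> float:
        return float(self.times[-1])

    def total_biomass(self) -> np.ndarray:
        return np.sum([x for x in self.biomass.values()], axis=0)

    def final_biomass(self, strain: str) -> float:
        return float(self.biomass[strain][-1])

    def final_concentration(self, metabolite: str) -> float:
        return float(self.medium[metabolite][-1])

    # -- export ---------------------------------------------------------
    def to_tidy_frame(self) -> pd.DataFrame:
        rows = []
        for s, x in self.biomass.items():
            rows.append(pd.DataFrame(
                {"time": self.times, "series": s, "variable": "biomass", "value": x}
            ))
        for m, c in self.medium.items():
            rows.append(pd.DataFrame(
                {"time": self.times, "series": m, "variable": "concentration", "value": c}
            ))
        return pd.concat(rows, ignore_index=True)

    def to_wide_frame(self) -> pd.DataFrame:
        data: dict[str, np.ndarray] = {"time": self.times}
        for s, x in self.biomass.items():
            data[f"biomass_{s}"] = x
        for m, c in self.medium.items():
            data[f"conc_{m}"] = c
        return pd.DataFrame(data)

    def write_csv(self, directory: str | Path, stem: str = "trace") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.to_tidy_frame().to_csv(directory / f"{stem}_tidy.csv", index=False)
        self.to_wide_frame().to_csv(directory / f"{stem}_wide.csv", index=False)


def uptake_bound(c: float, x: float, dt: float, spec: UptakeSpec | None) -> float:
    """Uptake bound (mmol gDW^-1 h^-1) for a pool at concentration ``c``.

    ``min(Vmax * saturation, c / (X * dt))`` with Michaelis-Menten
    saturation when the spec carries a Km.  Degenerate inputs (empty pool,
    zero biomass window) give 0.  Applied by the simulator as the negative
    lower bound of the exchange reaction.
    """
    if c <= 0 or x <= 0 or dt <= 0:
        return 0.0
    avail = c / (x * dt)
    if spec is None:
        return avail
    sat = c / (spec.km + c) if spec.km is not None else 1.0
    return min(spec.vmax * sat, avail)


def _exchange_info(
    model: StoichModel, layout: CommunityLayout, strain: str, pools: dict[str, float]
) -> list[tuple[str, float, float, str, UptakeSpec | None]]:
    """Static per-strain exchange table: (reaction id, lb, ub, pool id,
    uptake cap) for every exchange touching a tracked pool."""
    info = []
    for rxn, met in model.exchange_reactions():
        if met.id not in pools:
            continue  # unlimited metabolite
        spec = layout.uptake_spec(strain, met.id)
        if spec is None and rxn.lb == -math.inf:
            cap = None  # availability-limited only
        elif spec is None:
            cap = UptakeSpec(strain, met.id, vmax=-rxn.lb if rxn.lb < 0 else 0.0)
        else:
            cap = spec
        info.append((rxn.id, rxn.lb, rxn.ub, met.id, cap))
    return info


def _step_bounds(
    info: list[tuple[str, float, float, str, UptakeSpec | None]],
    pools: dict[str, float],
    x: float,
    dt: float,
) -> dict[str, tuple[float, float]]:
    """Per-step exchange bound overrides against the current pools."""
    overrides: dict[str, tuple[float, float]] = {}
    for rid, lb, ub, mid, cap in info:
        bound = uptake_bound(pools[mid], x, dt, cap)
        overrides[rid] = (max(lb, -bound), ub)
    return overrides


def simulate(
    models: Mapping[str, StoichModel],
    layout: CommunityLayout,
    seed: int = 0,
) -> SimulationTrace:
    """Run the community dynamic simulation.

    ``models`` maps strain id to its stoichiometric model; every strain in
    the layout must be present.  The strain execution order is re-permuted
    each step with a generator seeded by ``seed``: identical seeds give
    bit-identical traces.
    """
    missing = [s for s in layout.initial_biomass if s not in models]
    if missing:
        raise LayoutError(f"layout references strains without models: {missing}")

    rng = np.random.default_rng(seed)
    strains = list(layout.initial_biomass)
    n_steps = int(round(layout.horizon / layout.dt))
    dt = layout.dt

    X = {s: float(layout.initial_biomass[s]) for s in strains}
    pools = {m: float(c) for m, c in layout.medium.items()}
    initial_pools = dict(pools)

    biomass = {s: np.empty(n_steps + 1) for s in strains}
    medium = {m: np.empty(n_steps + 1) for m in pools}
    mu_series = {s: np.zeros(n_steps) for s in strains}
    status = {s: [] for s in strains}
    for s in strains:
        biomass[s][0] = X[s]
    for m in pools:
        medium[m][0] = pools[m]

    ex_info = {s: _exchange_info(models[s], layout, s, pools) for s in strains}
    tracked = {s: [(rid, mid) for rid, _, _, mid, _ in ex_info[s]] for s in strains}

    # memoise FBA solves on identical effective bounds (common while a
    # strain is Vmax-limited rather than availability-limited)
    cache: dict[tuple, FluxSolution] = {}

    def solve_cached(strain: str, overrides: dict[str, tuple[float, float]]) -> FluxSolution:
        key = (strain, tuple(sorted((r, round(lo, 12), round(hi, 12))
                                    for r, (lo, hi) in overrides.items())))
        sol = cache.get(key)
        if sol is None:
            sol = solve_fba(models[strain], bound_overrides=overrides)
            cache[key] = sol
        return sol

    transfer = layout.serial_transfer
    next_transfer = transfer.interval if transfer is not None else math.inf

    for k in range(n_steps):
        order = rng.permutation(len(strains))
        mu_step = {s: 0.0 for s in strains}
        if layout.proportional_split:
            # alternative rule: every strain sees the same start-of-step
            # pools, demands are scaled down if a pool oversubscribes
            snapshot = dict(pools)
            demands: dict[str, dict[str, float]] = {}
            sols: dict[str, FluxSolution] = {}
            for i in order:
                s = strains[i]
                if X[s] <= 0:
                    status[s].append("ok")
                    continue
                overrides = _step_bounds(ex_info[s], snapshot, X[s], dt)
                sol = solve_cached(s, overrides)
                if not sol.ok:
                    status[s].append("infeasible-zero-growth")
                    continue
                status[s].append("ok")
                sols[s] = sol
                demands[s] = {}
                for rid, mid in tracked[s]:
                    demands[s][mid] = sol.fluxes[rid] * X[s] * dt
            scale = {}
            for m in pools:
                drawn = -sum(min(d.get(m, 0.0), 0.0) for d in demands.values())
                scale[m] = min(1.0, pools[m] / drawn) if drawn > pools[m] > 0 else 1.0
            for s, sol in sols.items():
                f = min((scale[m] for m, d in demands[s].items() if d < 0), default=1.0)
                mu_step[s] = f * float(sol.objective_value)
                for m, d in demands[s].items():
                    pools[m] = max(0.0, pools[m] + f * d)
        else:
            for i in order:
                s = strains[i]
                if X[s] <= 0:
                    status[s].append("ok")
                    continue
                overrides = _step_bounds(ex_info[s], pools, X[s], dt)
                sol = solve_cached(s, overrides)
                if not sol.ok:
                    status[s].append("infeasible-zero-growth")
                    continue
                status[s].append("ok")
                mu_step[s] = float(sol.objective_value)
                for rid, mid in tracked[s]:
                    pools[mid] += sol.fluxes[rid] * X[s] * dt
                    if pools[mid] < POOL_CLAMP_TOL:
                        pools[mid] = 0.0

        t_next = (k + 1) * dt
        for s in strains:
            mu_series[s][k] = mu_step[s]
            X[s] = max(0.0, X[s] * (1.0 + (mu_step[s] - layout.death_rate) * dt))
        if transfer is not None and t_next >= next_transfer - 1e-9:
            for s in strains:
                X[s] *= transfer.dilution
            pools.update(initial_pools)
            next_transfer += transfer.interval
        for s in strains:
            biomass[s][k + 1] = X[s]
        for m in pools:
            medium[m][k + 1] = pools[m]

    times = np.arange(n_steps + 1) * dt
    meta = {
        "seed": seed,
        "dt": dt,
        "horizon": layout.horizon,
        "death_rate": layout.death_rate,
        "sharing": "proportional" if layout.proportional_split else "sequential",
    }
    return SimulationTrace(
        times=times, biomass=biomass, medium=medium, mu=mu_series,
        status=status, meta=meta,
    )


def effective_growth_rate(
    trace: SimulationTrace,
    strain: str | None = None,
    window: tuple[float, float] | None = None,
) -> float:
    """Effective growth rate (h^-1): least-squares slope of ln X over a
    time window.

    ``strain=None`` uses total community biomass.  A flat (non-growing)
    series returns 0.  If biomass hits zero inside the window, the fit is
    restricted to the positive prefix (with a warning); an all-zero series
    returns 0.
    """
    x = trace.total_biomass() if strain is None else trace.biomass[strain]
    t = trace.times
    if window is None:
        lo, hi = float(t[0]), float(t[-1])
    else:
        lo, hi = window
        if lo < t[0] - 1e-9 or hi > t[-1] + 1e-9 or hi <= lo:
            raise ValueError(
                f"window [{lo}, {hi}] outside trace range [{t[0]}, {t[-1]}]"
            )
    mask = (t >= lo - 1e-9) & (t <= hi + 1e-9)
    tw, xw = t[mask], x[mask]
    if np.any(xw <= 0):
        import warnings

        first_bad = int(np.argmax(xw <= 0))
        if first_bad < 2:
            return 0.0
        warnings.warn(
            f"biomass reaches zero inside window; fitting positive prefix "
            f"({first_bad} points)",
            stacklevel=2,
        )
        tw, xw = tw[:first_bad], xw[:first_bad]
    logx = np.log(xw)
    if np.allclose(logx, logx[0], atol=1e-15):
        return 0.0
    slope = np.polyfit(tw, logx, 1)[0]
    return float(slope)
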