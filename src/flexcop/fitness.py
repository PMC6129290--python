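"""Fitness functions for scoring simulated consortium configurations.

The registry covers the standard optimisation goals of consortium design:
terminal product titre, biomass yield on the limiting carbon source,
community growth rate, times to degradation / stationary phase / resource
exhaustion, total biomass, and *parallel growth stability* — the maximin
per-strain effective growth rate, which rewards configurations where every
strain keeps up and punishes washout of any member with a sentinel.

Because replicate simulations of the same configuration differ (strain
execution order is randomised), a configuration's fitness is the mean over
``n_replicates`` seeded runs; the standard deviation (population
convention, ddof=0) is recorded alongside, and auxiliary metrics (final
pool concentrations, per-strain effective growth rates, time to
stationary) are kept for the search history.

Composites are weighted sums of normalised components; minimised kinds
enter with a negative sign, so a composite is always maximised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .configspace import (
    ConfigSpace,
    ConsortiumConfig,
    apply_config,
    check_physiology,
)
from .dfba import CommunityLayout, SimulationTrace, effective_growth_rate, simulate
from .stoich import StoichModel

__all__ = [
    "METRIC_KINDS",
    "SENTINEL_FITNESS",
    "MetricSpec",
    "CompositeSpec",
    "FitnessResult",
    "compute_metric",
    "composite",
    "metric_score",
    "evaluate_config",
]

#: worst-possible fitness assigned to rejected / washed-out configurations
SENTINEL_FITNESS = -1e9

MAX_KINDS = (
    "max_growth_rate",
    "max_yield",
    "max_metabolite",
    "parallel_growth_stability",
    "max_biomass",
)
MIN_KINDS = (
    "min_degradation_time",
    "min_time_to_stationary",
    "min_time_to_exhaustion",
)
METRIC_KINDS = MAX_KINDS + MIN_KINDS


@dataclass(frozen=True)
class MetricSpec:
    """One optimisation goal.

    ``target_metabolite`` is required for the metabolite-referencing kinds
    (``max_metabolite``, ``max_yield`` — the limiting carbon source —,
    ``min_degradation_time`` and ``min_time_to_exhaustion``).  ``horizon``
    defaults to the full trace.  For ``min_time_to_stationary``,
    ``plateau_rel`` and ``plateau_steps`` define stationary-phase
    detection: relative per-step community biomass increase below
    ``plateau_rel`` for ``plateau_steps`` consecutive steps.
    ``washout_fraction`` (stability kind) marks a strain as washed out
    when its final biomass falls below that fraction of its initial.
    """

    kind: str
    target_metabolite: str | None = None
    horizon: float | None = None
    threshold: float = 1e-9          # "exhausted/degraded" concentration
    plateau_rel: float = 1e-3        # < 0.1% growth per step
    plateau_steps: int = 5
    washout_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in METRIC_KINDS:
            raise ValueError(f"unknown metric kind {self.kind!r}")
        needs_met = (
            "max_metabolite",
            "max_yield",
            "min_degradation_time",
            "min_time_to_exhaustion",
        )
        if self.kind in needs_met and self.target_metabolite is None:
            raise ValueError(f"metric {self.kind!r} needs a target metabolite")

    @property
    def minimized(self) -> bool:
        return self.kind in MIN_KINDS


@dataclass(frozen=True)
class CompositeSpec:
    """Weighted sum of normalised metrics, maximised as a whole."""

    components: tuple[tuple[MetricSpec, float], ...]
    normalization: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        comps = tuple((m, float(w)) for m, w in self.components)
        object.__setattr__(self, "components", comps)
        if not comps or any(w < 0 for _, w in comps):
            raise ValueError("composite needs weights >= 0")
        if not any(w > 0 for _, w in comps):
            raise ValueError("composite needs at least one positive weight")
        norm = self.normalization
        if norm is None:
            norm = tuple(1.0 for _ in comps)
        norm = tuple(float(s) for s in norm)
        if len(norm) != len(comps):
            raise ValueError("one normalization scale per component required")
        if any(s == 0 for s in norm):
            raise ValueError("zero normalization scale")
        object.__setattr__(self, "normalization", norm)


@dataclass(frozen=True)
class FitnessResult:
    mean: float
    sd: float
    replicate_values: tuple[float, ...]
    aux_metrics: dict = field(default_factory=dict)

    @property
    def rejected(self) -> bool:
        return bool(self.aux_metrics.get("rejected", False))


# ---------------------------------------------------------------------------
# metric computation
# ---------------------------------------------------------------------------

def _horizon_index(trace: SimulationTrace, horizon: float | None) -> int:
    if horizon is None:
        return len(trace.times) - 1
    if horizon > trace.horizon + 1e-9:
        raise ValueError(
            f"metric horizon {horizon} exceeds trace horizon {trace.horizon}"
        )
    return int(np.argmin(np.abs(trace.times - horizon)))


def _first_time(trace: SimulationTrace, mask: np.ndarray, default: float) -> float:
    idx = np.flatnonzero(mask)
    return float(trace.times[idx[0]]) if idx.size else default


def time_to_stationary(trace: SimulationTrace, spec: MetricSpec) -> float:
    """First time community biomass grows < ``plateau_rel`` per step for
    ``plateau_steps`` consecutive steps; the horizon if never."""
    total = trace.total_biomass()
    rel = np.abs(np.diff(total)) / np.maximum(total[:-1], 1e-30)
    flat = rel < spec.plateau_rel
    run = 0
    for k, f in enumerate(flat):
        run = run + 1 if f else 0
        if run >= spec.plateau_steps:
            return float(trace.times[k + 2 - spec.plateau_steps])
    return trace.horizon


def compute_metric(trace: SimulationTrace, spec: MetricSpec) -> float:
    """Evaluate one metric on a trace.

    Minimised kinds return the (positive) time — the caller negates.
    ``parallel_growth_stability`` returns ``-inf`` when any strain washes
    out.
    """
    k = spec.kind
    end = _horizon_index(trace, spec.horizon)

    if k == "max_metabolite":
        if spec.target_metabolite not in trace.medium:
            raise KeyError(
                f"metabolite {spec.target_metabolite!r} is not tracked in the trace"
            )
        return float(trace.medium[spec.target_metabolite][end])

    if k == "max_biomass":
        return float(trace.total_biomass()[end])

    if k == "max_yield":
        if spec.target_metabolite not in trace.medium:
            raise KeyError(
                f"metabolite {spec.target_metabolite!r} is not tracked in the trace"
            )
        series = trace.medium[spec.target_metabolite]
        consumed = float(series[0] - series[end])
        gained = float(trace.total_biomass()[end] - trace.total_biomass()[0])
        if consumed <= 0:
            return 0.0
        return gained / consumed

    if k == "max_growth_rate":
        t_end = trace.times[end]
        return effective_growth_rate(trace, None, (0.0, float(t_end)))

    if k == "parallel_growth_stability":
        rates = []
        for s in trace.strains:
            x0, x_end = trace.biomass[s][0], trace.biomass[s][end]
            if x0 <= 0 or x_end < spec.washout_fraction * x0:
                return -math.inf
            rates.append(effective_growth_rate(trace, s, (0.0, float(trace.times[end]))))
        return float(min(rates))

    if k == "min_degradation_time" or k == "min_time_to_exhaustion":
        if spec.target_metabolite not in trace.medium:
            raise KeyError(
                f"metabolite {spec.target_metabolite!r} is not tracked in the trace"
            )
        series = trace.medium[spec.target_metabolite]
        return _first_time(trace, series <= spec.threshold, default=trace.horizon)

    if k == "min_time_to_stationary":
        return time_to_stationary(trace, spec)

    raise AssertionError(k)


def composite(trace: SimulationTrace, spec: CompositeSpec) -> float:
    """Weighted sum of normalised metrics (minimised kinds negated)."""
    total = 0.0
    for (metric, weight), scale in zip(spec.components, spec.normalization):
        value = compute_metric(trace, metric) / scale
        total += weight * (-value if metric.minimized else value)
    return total


def metric_score(trace: SimulationTrace, spec: "MetricSpec | CompositeSpec") -> float:
    """Scalar score on the maximise scale for either spec flavour."""
    if isinstance(spec, CompositeSpec):
        return composite(trace, spec)
    value = compute_metric(trace, spec)
    return -value if spec.minimized else value


# ---------------------------------------------------------------------------
# configuration scoring
# ---------------------------------------------------------------------------

def _aux_from_traces(traces: Sequence[SimulationTrace]) -> dict:
    aux: dict = {}
    if not traces:
        return aux
    pools = traces[0].medium.keys()
    for m in pools:
        aux[f"final_{m}"] = float(np.mean([t.final_concentration(m) for t in traces]))
    for s in traces[0].strains:
        aux[f"gr_{s}"] = float(np.mean([effective_growth_rate(t, s) for t in traces]))
        aux[f"final_biomass_{s}"] = float(np.mean([t.final_biomass(s) for t in traces]))
    stat_spec = MetricSpec(kind="min_time_to_stationary")
    aux["time_to_stationary"] = float(
        np.mean([time_to_stationary(t, stat_spec) for t in traces])
    )
    return aux


def evaluate_config(
    config: ConsortiumConfig,
    space: ConfigSpace,
    models: Mapping[str, StoichModel],
    layout_template: CommunityLayout,
    fitness: "MetricSpec | CompositeSpec",
    n_replicates: int = 3,
    base_seed: int = 0,
) -> FitnessResult:
    """Score one configuration: physiology check, ``n_replicates`` seeded
    simulations (seeds ``base_seed .. base_seed+n-1``), replicate mean/sd.

    Inadmissible configurations are not simulated; they (and replicates
    whose score is non-finite, e.g. washout under the stability goal)
    receive :data:`SENTINEL_FITNESS`.
    """
    adm = check_physiology(config, space.predicates)
    if not adm.admissible:
        return FitnessResult(
            mean=SENTINEL_FITNESS,
            sd=0.0,
            replicate_values=(),
            aux_metrics={"rejected": True, "reason": adm.reason, "n_simulations": 0},
        )
    sim_models, layout = apply_config(config, space, models, layout_template)
    traces = []
    values = []
    for r in range(n_replicates):
        trace = simulate(sim_models, layout, seed=base_seed + r)
        traces.append(trace)
        v = metric_score(trace, fitness)
        values.append(max(v, SENTINEL_FITNESS) if math.isfinite(v) else SENTINEL_FITNESS)
    arr = np.asarray(values, dtype=float)
    aux = _aux_from_traces(traces)
    aux["n_simulations"] = n_replicates
    if np.all(arr <= SENTINEL_FITNESS):
        aux["all_infeasible"] = True
    return FitnessResult(
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=0)),
        replicate_values=tuple(float(v) for v in values),
        aux_metrics=aux,
    )
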