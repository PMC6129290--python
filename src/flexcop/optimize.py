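"""Search over a discrete configuration space.

Two search strategies share one record/result format:

* :func:`run_exhaustive` — evaluate every admissible configuration once.
  Exact but only viable on small grids; in the test-suite it is the oracle
  the stochastic search is compared against.
* :func:`run_smbo` — sequential model-based optimisation in the SMAC
  family: a seeded random warm start, then, per iteration, an ensemble of
  regression trees is fitted to the (configuration, mean fitness) history,
  a candidate set (global random draws plus all one-parameter neighbours
  of the incumbent — the "iterated local search" ingredient) is scored by
  expected improvement, and the best candidate is evaluated.  Because the
  objective is a noisy replicate mean, a challenger must match the
  incumbent's replicate count (intensification) before it can take over.

The objective protocol: ``objective(config, seed) -> float`` returns one
replicate value; deterministic objectives may ignore the seed.  The
optimiser aggregates replicates itself, so exhaustive and SMBO searches
score configurations identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.ensemble import RandomForestRegressor

from .configspace import ConfigSpace, ConsortiumConfig, check_physiology
from .fitness import SENTINEL_FITNESS

__all__ = [
    "SearchBudget",
    "EvaluationRecord",
    "SearchResult",
    "Objective",
    "run_exhaustive",
    "run_smbo",
    "expected_improvement",
    "records_from_frame",
    "history_frame",
    "save_history",
    "load_history",
]

Objective = Callable[[ConsortiumConfig, int], float]

EXHAUSTIVE_CAP = 10_000


@dataclass(frozen=True)
class SearchBudget:
    """Evaluation budget and reproducibility control for the search."""

    max_evaluations: int = 500
    replicates_per_eval: int = 1
    seed: int = 0
    initial_random: int = 10
    n_random_candidates: int = 1000
    n_trees: int = 30
    intensify: bool = True

    def __post_init__(self) -> None:
        if self.max_evaluations < 1:
            raise ValueError("max_evaluations must be >= 1")
        if self.initial_random > self.max_evaluations:
            raise ValueError("initial_random cannot exceed max_evaluations")
        if self.replicates_per_eval < 1:
            raise ValueError("replicates_per_eval must be >= 1")


@dataclass
class EvaluationRecord:
    iteration: int
    config: ConsortiumConfig
    fitness_mean: float
    fitness_sd: float
    n_replicates: int
    admissible: bool = True
    aux_metrics: dict = field(default_factory=dict)


@dataclass
class SearchResult:
    incumbent: ConsortiumConfig
    incumbent_fitness: float
    history: list[EvaluationRecord]
    convergence: list[float]

    def history_frame(self) -> pd.DataFrame:
        return history_frame(self.history)


def history_frame(history: Sequence[EvaluationRecord]) -> pd.DataFrame:
    """Flatten records into the run-history table: one row per evaluation,
    one column per parameter, plus fitness and auxiliary metric columns."""
    rows = []
    for rec in history:
        row: dict = {"iteration": rec.iteration}
        row.update(rec.config.assignment)
        row["fitness_mean"] = rec.fitness_mean
        row["fitness_sd"] = rec.fitness_sd
        row["n_replicates"] = rec.n_replicates
        row["admissible"] = rec.admissible
        for k, v in rec.aux_metrics.items():
            if isinstance(v, (int, float, bool, str)):
                row[k] = v
        rows.append(row)
    return pd.DataFrame(rows)


def save_history(history: Sequence[EvaluationRecord], path) -> None:
    history_frame(history).to_csv(path, sep="\t", index=False)


def load_history(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def expected_improvement(mean: float, sd: float, incumbent_value: float) -> float:
    """Closed-form expected improvement for maximisation.

    ``(m - b) * Phi(z) + s * phi(z)`` with ``z = (m - b)/s``; when the
    predictive sd is zero this degenerates to ``max(m - b, 0)``.
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    imp = mean - incumbent_value
    if sd == 0.0:
        return max(imp, 0.0)
    z = imp / sd
    return float(imp * norm.cdf(z) + sd * norm.pdf(z))


# ---------------------------------------------------------------------------
# exhaustive search
# ---------------------------------------------------------------------------

def _call_objective(
    objective: Objective, config: ConsortiumConfig, seeds: Sequence[int]
) -> list[float]:
    values = []
    for s in seeds:
        v = float(objective(config, int(s)))
        values.append(v if math.isfinite(v) else SENTINEL_FITNESS)
    return values


def run_exhaustive(
    space: ConfigSpace,
    objective: Objective,
    replicates_per_eval: int = 1,
    seed: int = 0,
    cap: int = EXHAUSTIVE_CAP,
) -> SearchResult:
    """Evaluate every admissible configuration once (deterministic order).

    Ties in mean fitness are broken by enumeration order.  Spaces above
    ``cap`` configurations are refused — use :func:`run_smbo` there.
    """
    size = space.size()
    if size == 0:
        raise ValueError("empty configuration space")
    if size > cap:
        raise ValueError(
            f"space has {size} configurations (> cap {cap}); use run_smbo"
        )
    history: list[EvaluationRecord] = []
    best: EvaluationRecord | None = None
    convergence: list[float] = []
    for it, config in enumerate(space.enumerate()):
        adm = check_physiology(config, space.predicates)
        if adm.admissible:
            seeds = [seed + it * replicates_per_eval + r for r in range(replicates_per_eval)]
            values = _call_objective(objective, config, seeds)
            arr = np.asarray(values)
            rec = EvaluationRecord(
                iteration=it,
                config=config,
                fitness_mean=float(arr.mean()),
                fitness_sd=float(arr.std(ddof=0)),
                n_replicates=len(values),
                admissible=True,
            )
        else:
            rec = EvaluationRecord(
                iteration=it,
                config=config,
                fitness_mean=SENTINEL_FITNESS,
                fitness_sd=0.0,
                n_replicates=0,
                admissible=False,
                aux_metrics={"rejected": True, "reason": adm.reason},
            )
        history.append(rec)
        if best is None or rec.fitness_mean > best.fitness_mean:
            best = rec
        convergence.append(best.fitness_mean)
    assert best is not None
    return SearchResult(
        incumbent=best.config,
        incumbent_fitness=best.fitness_mean,
        history=history,
        convergence=convergence,
    )


# ---------------------------------------------------------------------------
# SMBO
# ---------------------------------------------------------------------------

def _neighbors(space: ConfigSpace, config: ConsortiumConfig) -> list[ConsortiumConfig]:
    """All configurations differing from ``config`` in exactly one
    parameter (any other value of that parameter's domain), ordered by
    grid distance so that near moves precede far ones."""
    out = []
    for s in space.specs:
        i = s.domain.index(config[s.name])
        order = sorted(range(len(s.domain)), key=lambda j: (abs(j - i), j))
        for j in order:
            if j != i:
                assignment = dict(config.assignment)
                assignment[s.name] = s.domain[j]
                out.append(ConsortiumConfig(assignment))
    return out


def _random_config(space: ConfigSpace, rng: np.random.Generator) -> ConsortiumConfig:
    return ConsortiumConfig(
        {s.name: s.domain[rng.integers(len(s.domain))] for s in space.specs}
    )


class _History:
    """Merged per-configuration replicate bookkeeping for SMBO."""

    def __init__(self) -> None:
        self.records: list[EvaluationRecord] = []
        self.replicates: dict[tuple, list[float]] = {}
        self.configs: dict[tuple, ConsortiumConfig] = {}

    def seen(self, config: ConsortiumConfig) -> bool:
        return config.key() in self.replicates

    def mean(self, config: ConsortiumConfig) -> float:
        return float(np.mean(self.replicates[config.key()]))

    def count(self, config: ConsortiumConfig) -> int:
        return len(self.replicates[config.key()])

    def add(
        self, iteration: int, config: ConsortiumConfig, values: Sequence[float],
        admissible: bool = True, aux: dict | None = None,
    ) -> EvaluationRecord:
        key = config.key()
        self.replicates.setdefault(key, []).extend(values)
        self.configs[key] = config
        merged = self.replicates[key]
        rec = EvaluationRecord(
            iteration=iteration,
            config=config,
            fitness_mean=float(np.mean(merged)) if merged else SENTINEL_FITNESS,
            fitness_sd=float(np.std(merged)) if merged else 0.0,
            n_replicates=len(merged),
            admissible=admissible,
            aux_metrics=aux or {},
        )
        self.records.append(rec)
        return rec


def records_from_frame(frame: pd.DataFrame, space: ConfigSpace) -> list[EvaluationRecord]:
    """Rebuild evaluation records from a saved history table (for
    ``run_smbo(..., resume=...)``)."""
    records = []
    for _, row in frame.iterrows():
        config = ConsortiumConfig({s.name: float(row[s.name]) for s in space.specs})
        records.append(
            EvaluationRecord(
                iteration=int(row.get("iteration", len(records))),
                config=config,
                fitness_mean=float(row["fitness_mean"]),
                fitness_sd=float(row.get("fitness_sd", 0.0)),
                n_replicates=int(row.get("n_replicates", 1)),
                admissible=bool(row.get("admissible", True)),
            )
        )
    return records


def run_smbo(
    space: ConfigSpace,
    objective: Objective,
    budget: SearchBudget,
    resume: Sequence[EvaluationRecord] | None = None,
) -> SearchResult:
    """Surrogate-guided stochastic search; reproducible from ``budget.seed``.

    Inadmissible configurations are recorded with the sentinel fitness and
    never simulated.  History length is bounded by ``max_evaluations``
    (each evaluation event = one batch of replicates on one configuration).
    ``resume`` preloads records from an earlier run: they seed the
    surrogate and the incumbent but do not count against the budget.
    """
    rng = np.random.default_rng(budget.seed)
    size = space.size()
    n_evals = 0
    hist = _History()
    incumbent: ConsortiumConfig | None = None
    convergence: list[float] = []

    if resume:
        for rec in resume:
            values = [rec.fitness_mean] * max(rec.n_replicates, 1)
            hist.add(rec.iteration, rec.config, values, admissible=rec.admissible)
            if incumbent is None or hist.mean(rec.config) > hist.mean(incumbent):
                incumbent = rec.config

    def fresh_seeds(n: int) -> list[int]:
        return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]

    def evaluate(config: ConsortiumConfig, n_rep: int) -> None:
        nonlocal n_evals, incumbent
        adm = check_physiology(config, space.predicates)
        if adm.admissible:
            values = _call_objective(objective, config, fresh_seeds(n_rep))
            hist.add(n_evals, config, values, admissible=True)
        else:
            hist.add(
                n_evals, config, [SENTINEL_FITNESS], admissible=False,
                aux={"rejected": True, "reason": adm.reason},
            )
        n_evals += 1
        if incumbent is None or hist.mean(config) > hist.mean(incumbent):
            if incumbent is None:
                incumbent = config
            elif budget.intensify and hist.count(config) < hist.count(incumbent):
                pass  # challenger must first match the incumbent's replicates
            else:
                incumbent = config
        convergence.append(hist.mean(incumbent))

    # --- warm start: distinct random configurations --------------------
    n_init = min(budget.initial_random, budget.max_evaluations, size)
    attempts = 0
    while len(hist.replicates) < n_init and attempts < 50 * n_init:
        config = _random_config(space, rng)
        attempts += 1
        if not hist.seen(config):
            evaluate(config, budget.replicates_per_eval)

    # --- guided iterations ---------------------------------------------
    refresh_clock = 0
    while n_evals < budget.max_evaluations:
        assert incumbent is not None
        # promote any fully-replicated configuration that now beats the
        # incumbent (its mean may have dropped after a refresh)
        if budget.intensify:
            for key, vals in hist.replicates.items():
                cfg = hist.configs[key]
                if (
                    cfg != incumbent
                    and len(vals) >= hist.count(incumbent)
                    and np.mean(vals) > hist.mean(incumbent)
                ):
                    incumbent = cfg
        # intensification pass: top up the challenger from the previous
        # round if it looked better but had fewer replicates
        pending = None
        if budget.intensify:
            for key, vals in hist.replicates.items():
                cfg = hist.configs[key]
                if (
                    cfg != incumbent
                    and np.mean(vals) > hist.mean(incumbent)
                    and len(vals) < hist.count(incumbent)
                ):
                    pending = cfg
                    break
        if pending is not None:
            need = hist.count(incumbent) - hist.count(pending)
            evaluate(pending, min(need, budget.replicates_per_eval))
            continue

        # incumbent refresh: under a noisy objective the incumbent earns
        # extra replicates over time, so a lucky challenger must survive
        # an equally deep replicate mean before taking over
        refresh_clock += 1
        if (
            budget.intensify
            and budget.replicates_per_eval > 1
            and refresh_clock % 2 == 0
            and hist.count(incumbent) < 4 * budget.replicates_per_eval
        ):
            evaluate(incumbent, 1)
            continue

        # candidate order matters: one-parameter neighbours of the
        # incumbent come first so that EI ties (flat surrogate early on)
        # resolve into local uphill moves — the iterated-local-search core
        candidates: list[ConsortiumConfig] = []
        seen_keys = set()
        for c in _neighbors(space, incumbent):
            if not hist.seen(c) and c.key() not in seen_keys:
                candidates.append(c)
                seen_keys.add(c.key())
        for _ in range(budget.n_random_candidates):
            c = _random_config(space, rng)
            if not hist.seen(c) and c.key() not in seen_keys:
                candidates.append(c)
                seen_keys.add(c.key())
        if size <= budget.n_random_candidates:
            # small spaces: candidate set is every unevaluated configuration,
            # so a budget >= |space| provably covers the grid
            for c in space.enumerate():
                if not hist.seen(c) and c.key() not in seen_keys:
                    candidates.append(c)
                    seen_keys.add(c.key())
        if not candidates:
            # space exhausted: re-evaluate the incumbent with a fresh replicate
            evaluate(incumbent, budget.replicates_per_eval)
            continue

        X = np.array([space.encode(hist.configs[k]) for k in hist.replicates])
        y = np.array([float(np.mean(v)) for v in hist.replicates.values()])
        if len(np.unique(y)) < 2 or len(y) < 2:
            chosen = candidates[int(rng.integers(len(candidates)))]
        else:
            forest = RandomForestRegressor(
                n_estimators=budget.n_trees,
                random_state=int(rng.integers(2**31 - 1)),
                bootstrap=True,
            )
            forest.fit(X, y)
            C = np.array([space.encode(c) for c in candidates])
            per_tree = np.stack([t.predict(C) for t in forest.estimators_])
            mu = per_tree.mean(axis=0)
            sd = per_tree.std(axis=0)
            b = hist.mean(incumbent)
            ei = np.array(
                [expected_improvement(m, s, b) for m, s in zip(mu, sd)]
            )
            order = np.lexsort((-mu, -ei))  # best EI, ties by predicted mean
            chosen = candidates[int(order[0])]
        evaluate(chosen, budget.replicates_per_eval)

    assert incumbent is not None
    return SearchResult(
        incumbent=incumbent,
        incumbent_fitness=hist.mean(incumbent),
        history=hist.records,
        convergence=convergence,
    )
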