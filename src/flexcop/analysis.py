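"""Mining the evaluated-configuration history.

After a search, the history table (one row per evaluated configuration,
one column per parameter, plus the fitness) is itself a dataset: which
parameters drive fitness, what do the best configurations have in common,
and can the top fraction be separated by simple decision rules?  This
module provides those reports, plus a classifier for community growth
curve *profiles* (coexistence / single survivor / no growth /
undifferentiated) used when sweeping a space of competing phenotypes.

Rule induction is deliberately a transparent exhaustive single-threshold
search (optionally greedy two-rule conjunctions) rather than a generic
tree learner: results are deterministic and directly checkable against a
brute-force oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .dfba import SimulationTrace

__all__ = [
    "CorrelationTable",
    "DecisionRule",
    "ProfileThresholds",
    "AnalysisReport",
    "correlation_report",
    "top_fraction_profile",
    "induce_rules",
    "classify_profile",
    "profile_counts",
    "analyze_history",
]

FITNESS_COL = "fitness_mean"


def _param_columns(history: pd.DataFrame, params: Sequence[str] | None) -> list[str]:
    if params is not None:
        return list(params)
    reserved = {
        "iteration", FITNESS_COL, "fitness_sd", "n_replicates", "admissible",
    }
    return [
        c for c in history.columns
        if c not in reserved and pd.api.types.is_numeric_dtype(history[c])
        and not c.startswith(("final_", "gr_", "time_to_"))
    ]


def _admissible(history: pd.DataFrame) -> pd.DataFrame:
    if "admissible" in history.columns:
        return history[history["admissible"].astype(bool)]
    return history


@dataclass(frozen=True)
class CorrelationTable:
    """Pearson correlations parameter-vs-fitness and pairwise.

    ``matrix`` is indexed/columned by parameter names plus the fitness
    column; entries for constant columns are flagged in ``defined`` (False)
    and set to 0 in the matrix rather than propagating NaN.
    """

    matrix: pd.DataFrame
    defined: pd.DataFrame

    def fitness_correlations(self) -> pd.Series:
        return self.matrix[FITNESS_COL].drop(FITNESS_COL)

    def is_defined(self, a: str, b: str) -> bool:
        return bool(self.defined.loc[a, b])


def correlation_report(
    history: pd.DataFrame, params: Sequence[str] | None = None
) -> CorrelationTable:
    """Pearson r for every parameter against fitness and pairwise.

    Requires at least 3 admissible records.  Constant columns yield
    undefined correlations, flagged rather than NaN.
    """
    df = _admissible(history)
    if len(df) < 3:
        raise ValueError(f"need >= 3 admissible records, got {len(df)}")
    cols = _param_columns(df, params) + [FITNESS_COL]
    X = df[cols].to_numpy(dtype=float)
    n = len(cols)
    mat = np.zeros((n, n))
    ok = np.zeros((n, n), dtype=bool)
    sd = X.std(axis=0)
    for i in range(n):
        for j in range(n):
            if i == j:
                mat[i, j], ok[i, j] = 1.0, sd[i] > 0
            elif sd[i] > 0 and sd[j] > 0:
                r = np.corrcoef(X[:, i], X[:, j])[0, 1]
                mat[i, j], ok[i, j] = float(r), True
    matrix = pd.DataFrame(mat, index=cols, columns=cols)
    defined = pd.DataFrame(ok, index=cols, columns=cols)
    return CorrelationTable(matrix=matrix, defined=defined)


def _top_mask(df: pd.DataFrame, fraction: float) -> pd.Series:
    """Boolean mask of the top ``fraction`` records by fitness, ties at
    the cutoff included."""
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    n_top = math.ceil(fraction * len(df))
    cutoff = df[FITNESS_COL].sort_values(ascending=False).iloc[n_top - 1]
    return df[FITNESS_COL] >= cutoff


def top_fraction_profile(
    history: pd.DataFrame,
    fraction: float = 0.05,
    params: Sequence[str] | None = None,
) -> dict[str, float]:
    """Parameter values shared by *every* record in the best ``fraction``.

    Returns ``{parameter: value}`` for parameters constant across the top
    set; an empty dict when nothing is shared.
    """
    df = _admissible(history)
    if df.empty:
        raise ValueError("empty history")
    top = df[_top_mask(df, fraction)]
    profile = {}
    for p in _param_columns(df, params):
        vals = top[p].unique()
        if len(vals) == 1:
            profile[p] = float(vals[0])
    return profile


@dataclass(frozen=True)
class DecisionRule:
    """Single-threshold rule ``param <= t`` / ``param >= t`` (or a
    conjunction of two) separating top configurations from the rest."""

    conditions: tuple[tuple[str, str, float], ...]  # (param, "<="|">=", t)
    accuracy: float  # balanced accuracy on the labelled history

    def describe(self) -> str:
        return " and ".join(f"{p} {op} {t:g}" for p, op, t in self.conditions)

    def applies(self, row) -> bool:
        return all(
            (row[p] <= t) if op == "<=" else (row[p] >= t)
            for p, op, t in self.conditions
        )


def _balanced_accuracy(pred: np.ndarray, label: np.ndarray) -> float:
    pos, neg = label, ~label
    tpr = pred[pos].mean() if pos.any() else 0.0
    tnr = (~pred[neg]).mean() if neg.any() else 0.0
    return float((tpr + tnr) / 2)


def _best_rule_for_param(
    x: np.ndarray, label: np.ndarray, param: str
) -> tuple[tuple[str, str, float], float]:
    """Exhaustive scan over candidate thresholds (midpoints between sorted
    distinct values) and both directions."""
    values = np.unique(x)
    thresholds = (values[:-1] + values[1:]) / 2 if len(values) > 1 else values
    best = (param, "<=", float(values[0])), -1.0
    for t in thresholds:
        for op in ("<=", ">="):
            pred = x <= t if op == "<=" else x >= t
            acc = _balanced_accuracy(pred, label)
            if acc > best[1]:
                best = (param, op, float(t)), acc
    return best


def induce_rules(
    history: pd.DataFrame,
    fraction: float = 0.1,
    min_accuracy: float = 0.9,
    params: Sequence[str] | None = None,
) -> list[DecisionRule]:
    """Decision rules separating the top ``fraction`` from the rest.

    For each parameter the single threshold maximising balanced accuracy
    is found by exhaustive search; rules above ``min_accuracy`` are
    returned sorted by accuracy (descending).  A greedy conjunction of the
    best rule with each other parameter's best co-rule is attempted and
    included when it beats both components.  A degenerate single-class
    labelling returns an empty list.
    """
    df = _admissible(history)
    if len(df) < 2:
        raise ValueError(f"need >= 2 records to induce rules, got {len(df)}")
    label = _top_mask(df, fraction).to_numpy()
    if label.all() or not label.any():
        return []
    cols = _param_columns(df, params)
    singles = []
    for p in cols:
        cond, acc = _best_rule_for_param(df[p].to_numpy(dtype=float), label, p)
        singles.append(DecisionRule(conditions=(cond,), accuracy=acc))
    singles.sort(key=lambda r: (-r.accuracy, r.conditions[0][0]))

    rules = [r for r in singles if r.accuracy >= min_accuracy]

    if singles:
        base = singles[0]
        base_pred = np.array([base.applies(row) for _, row in df.iterrows()])
        best_conj = None
        for p in cols:
            if p == base.conditions[0][0]:
                continue
            x = df[p].to_numpy(dtype=float)
            # refine on the subset predicted positive by the base rule
            cond, _ = _best_rule_for_param(x, label, p)
            pred = base_pred & (x <= cond[2] if cond[1] == "<=" else x >= cond[2])
            acc = _balanced_accuracy(pred, label)
            if acc > base.accuracy and (best_conj is None or acc > best_conj.accuracy):
                best_conj = DecisionRule(
                    conditions=(base.conditions[0], cond), accuracy=acc
                )
        if best_conj is not None and best_conj.accuracy >= min_accuracy:
            rules.append(best_conj)
            rules.sort(key=lambda r: -r.accuracy)
    return rules


# ---------------------------------------------------------------------------
# growth-curve profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProfileThresholds:
    """``growth_factor``: a strain counts as growing when its final biomass
    exceeds this multiple of its initial.  ``ancestor_tol``: maximum
    relative deviation between strain trajectories for the community to
    count as undifferentiated."""

    growth_factor: float = 2.0
    ancestor_tol: float = 0.05


PROFILE_CATEGORIES = ("coexistence", "single_survivor", "no_growth", "ancestor_like")


def classify_profile(
    trace: SimulationTrace, thresholds: ProfileThresholds = ProfileThresholds()
) -> str:
    """Classify a multi-strain growth curve.

    * ``no_growth`` — no strain multiplied its initial biomass by the
      growth factor;
    * ``single_survivor`` — exactly one did;
    * ``ancestor_like`` — several grew but their trajectories are pairwise
      within the relative tolerance (phenotypically undifferentiated);
    * ``coexistence`` — several grew along distinct trajectories.

    Categories are mutually exclusive and exhaustive.  Raises on
    single-strain traces: profiles describe communities.
    """
    strains = trace.strains
    if len(strains) < 2:
        raise ValueError("profile classification needs a multi-strain trace")
    growing = [
        s for s in strains
        if trace.final_biomass(s) > thresholds.growth_factor * trace.biomass[s][0]
    ]
    if not growing:
        return "no_growth"
    if len(growing) == 1:
        return "single_survivor"
    series = [trace.biomass[s] for s in strains]
    undifferentiated = True
    for i in range(len(series)):
        for j in range(i + 1, len(series)):
            a, b = series[i], series[j]
            denom = np.maximum(np.maximum(np.abs(a), np.abs(b)), 1e-30)
            if np.max(np.abs(a - b) / denom) > thresholds.ancestor_tol:
                undifferentiated = False
    return "ancestor_like" if undifferentiated else "coexistence"


def profile_counts(
    traces: Sequence[SimulationTrace],
    thresholds: ProfileThresholds = ProfileThresholds(),
) -> dict[str, int]:
    counts = {c: 0 for c in PROFILE_CATEGORIES}
    for t in traces:
        counts[classify_profile(t, thresholds)] += 1
    return counts


@dataclass(frozen=True)
class AnalysisReport:
    correlations: CorrelationTable
    top_profile: dict[str, float]
    rules: list[DecisionRule]
    profile_counts: dict[str, int] = field(default_factory=dict)

    def write_csv(self, directory) -> None:
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.correlations.matrix.to_csv(directory / "correlations.csv")
        pd.DataFrame(
            [{"rule": r.describe(), "accuracy": r.accuracy} for r in self.rules]
        ).to_csv(directory / "rules.csv", index=False)
        pd.Series(self.top_profile, name="value").to_csv(directory / "top_profile.csv")
        if self.profile_counts:
            pd.Series(self.profile_counts, name="count").to_csv(
                directory / "profile_counts.csv"
            )


def analyze_history(
    history: pd.DataFrame,
    top_fraction: float = 0.05,
    min_accuracy: float = 0.9,
    params: Sequence[str] | None = None,
) -> AnalysisReport:
    """One-call report: correlations, best-fraction profile, decision rules."""
    return AnalysisReport(
        correlations=correlation_report(history, params),
        top_profile=top_fraction_profile(history, top_fraction, params),
        rules=induce_rules(history, top_fraction, min_accuracy, params),
    )
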