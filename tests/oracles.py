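"""Independent oracles the implementation is checked against.

Each oracle deliberately takes the dumbest correct route: vertex
enumeration for LPs, direct textbook formulas for statistics, exhaustive
scans for rules.  They share no code with the implementation paths they
verify.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def fba_vertex_oracle(model, sense: str = "maximize", tol: float = 1e-9) -> float | None:
    """Optimal objective value by brute-force vertex enumeration of the
    bounded polytope {S.v = 0, couplings, lb <= v <= ub}.

    Returns None when no feasible vertex exists.  Only viable for toy
    models (combinatorial in the reaction count).
    """
    S, _mets, rxn_ids = model.stoichiometric_matrix()
    ridx = {r: j for j, r in enumerate(rxn_ids)}
    rows = [S]
    for c in model.couplings:
        row = np.zeros(len(rxn_ids))
        row[ridx[c.target]] = 1.0
        row[ridx[c.source]] = -c.ratio
        rows.append(row[None, :])
    A = np.vstack(rows)
    n = A.shape[1]
    rank = np.linalg.matrix_rank(A, tol=1e-10)
    n_fix = n - rank
    lbs = [r.lb for r in model.reactions]
    ubs = [r.ub for r in model.reactions]
    obj_idx = ridx[model.objective]
    sign = 1.0 if sense == "maximize" else -1.0

    best = None
    for fixed_vars in itertools.combinations(range(n), n_fix):
        bound_options = []
        for j in fixed_vars:
            opts = [b for b in (lbs[j], ubs[j]) if math.isfinite(b)]
            bound_options.append(sorted(set(opts)))
        if any(not o for o in bound_options):
            continue
        for vals in itertools.product(*bound_options):
            rows2 = [A]
            rhs = [np.zeros(A.shape[0])]
            for j, v in zip(fixed_vars, vals):
                e = np.zeros(n)
                e[j] = 1.0
                rows2.append(e[None, :])
                rhs.append([v])
            M = np.vstack(rows2)
            b = np.concatenate(rhs)
            x, residuals, rk, _ = np.linalg.lstsq(M, b, rcond=None)
            if rk < n:
                continue  # underdetermined: not a vertex
            if np.max(np.abs(M @ x - b)) > tol:
                continue  # inconsistent system
            if any(x[j] < lbs[j] - tol or x[j] > ubs[j] + tol for j in range(n)):
                continue
            val = sign * x[obj_idx]
            if best is None or val > best:
                best = val
    return None if best is None else sign * best


def pearson_oracle(x, y) -> float:
    """Pearson r by the direct moment formula."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mx, my = x.mean(), y.mean()
    cov = np.mean((x - mx) * (y - my))
    return float(cov / math.sqrt(np.mean((x - mx) ** 2) * np.mean((y - my) ** 2)))


def best_threshold_oracle(x, label) -> tuple[str, float, float]:
    """Exhaustive scan over *every* observed value as threshold, both
    directions; returns (op, threshold, balanced accuracy)."""
    x = np.asarray(x, dtype=float)
    label = np.asarray(label, dtype=bool)
    best = ("<=", float(x[0]), -1.0)
    candidates = np.unique(np.concatenate([x, (x[:-1] + x[1:]) / 2 if len(x) > 1 else x]))
    for t in candidates:
        for op in ("<=", ">="):
            pred = x <= t if op == "<=" else x >= t
            tpr = pred[label].mean() if label.any() else 0.0
            tnr = (~pred[~label]).mean() if (~label).any() else 0.0
            acc = (tpr + tnr) / 2
            if acc > best[2]:
                best = (op, float(t), float(acc))
    return best
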