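"""Deterministic LP/MILP solving on top of scipy's HiGHS interface.

Every extraction method in the package is an LP or MILP over the same
steady-state flux polytope, so a single thin wrapper suffices.  Problems are
stated in the conventional form

    optimize c.x  s.t.  A_eq.x = b_eq,  A_ub.x <= b_ub,  lb <= x <= ub

with an optional per-variable integrality vector for MILPs.  HiGHS with fixed
default options is deterministic, which the extraction methods rely on for
reproducible tie-breaking.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

__all__ = [
    "OptimizationError",
    "InfeasibleError",
    "UnboundedError",
    "solve_lp",
    "solve_milp",
]


class OptimizationError(RuntimeError):
    """Base class for solver failures."""


class InfeasibleError(OptimizationError):
    """The constraint system admits no solution."""


class UnboundedError(OptimizationError):
    """The objective is unbounded over the feasible region."""


def solve_lp(
    c,
    *,
    A_eq=None,
    b_eq=None,
    A_ub=None,
    b_ub=None,
    bounds=None,
    maximize: bool = False,
):
    """Solve an LP; return ``(x, objective_value)``.

    ``bounds`` is a sequence of ``(lb, ub)`` pairs.  Raises
    :class:`InfeasibleError` / :class:`UnboundedError` on the respective
    solver statuses (linprog status codes 2 and 3).
    """
    c = np.asarray(c, dtype=float)
    sign = -1.0 if maximize else 1.0
    res = linprog(
        sign * c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
    )
    if res.status == 2:
        raise InfeasibleError(f"LP infeasible: {res.message}")
    if res.status == 3:
        raise UnboundedError(f"LP unbounded: {res.message}")
    if not res.success:
        raise OptimizationError(f"LP solver failure (status {res.status}): {res.message}")
    return np.asarray(res.x, dtype=float), sign * float(res.fun)


def _solve_milp_once(c, A_eq, b_eq, A_ub, b_ub, bounds, integrality, maximize):
    c = np.asarray(c, dtype=float)
    sign = -1.0 if maximize else 1.0
    constraints = []
    if A_eq is not None and len(A_eq) > 0:
        b_eq = np.asarray(b_eq, dtype=float)
        constraints.append(LinearConstraint(np.asarray(A_eq, dtype=float), b_eq, b_eq))
    if A_ub is not None and len(A_ub) > 0:
        b_ub = np.asarray(b_ub, dtype=float)
        constraints.append(
            LinearConstraint(np.asarray(A_ub, dtype=float), -np.inf, b_ub)
        )
    if bounds is None:
        var_bounds = Bounds(-np.inf, np.inf)
    else:
        lbs = np.array([b[0] for b in bounds], dtype=float)
        ubs = np.array([b[1] for b in bounds], dtype=float)
        var_bounds = Bounds(lbs, ubs)
    res = milp(
        sign * c,
        constraints=constraints,
        bounds=var_bounds,
        integrality=np.asarray(integrality),
        # presolve can mis-handle the no-good cut rows added by the
        # verification loop (incumbents lost in postsolve); keep it off
        options={"mip_rel_gap": 0.0, "presolve": False},
    )
    if res.status == 2:
        raise InfeasibleError(f"MILP infeasible: {res.message}")
    if res.status == 3:
        raise UnboundedError(f"MILP unbounded: {res.message}")
    if res.x is None:
        raise OptimizationError(f"MILP solver failure (status {res.status}): {res.message}")
    return np.asarray(res.x, dtype=float), sign * float(res.fun)


def solve_milp(
    c,
    *,
    A_eq=None,
    b_eq=None,
    A_ub=None,
    b_ub=None,
    bounds=None,
    integrality=None,
    maximize: bool = False,
    verify: bool = True,
):
    """Solve a MILP exactly on its integer assignment; return ``(x, objective)``.

    ``integrality`` follows scipy's convention (0 continuous, 1 integer).

    Big-M couplings such as ``v <= M * y`` amplify the MIP solver's
    integrality tolerance by M, which can exceed the activation threshold the
    binaries encode and admit spurious "solutions" (e.g. a reaction counted
    as silent while carrying a small flux).  With ``verify`` enabled, the
    incumbent's rounded integer assignment is re-checked by an LP with the
    integers hard-fixed; if the exact value does not reproduce the claim, the
    problem is re-solved by an exact branch-and-bound over the integer
    variables in which every leaf is such a hard-fixed LP — simplex
    feasibility tolerances are absolute (~1e-7), so no leak survives.
    """
    c = np.asarray(c, dtype=float)
    n = c.size
    if integrality is None:
        integrality = np.zeros(n)
    integrality = np.asarray(integrality)
    int_idx = np.where(integrality > 0)[0]
    if not verify or int_idx.size == 0:
        return _solve_milp_once(c, A_eq, b_eq, A_ub, b_ub, bounds, integrality, maximize)

    x, claimed = _solve_milp_once(c, A_eq, b_eq, A_ub, b_ub, bounds, integrality, maximize)
    tol = 1e-6 * max(1.0, abs(claimed))
    fixed = list(bounds) if bounds is not None else [(None, None)] * n
    for i in int_idx:
        val = float(round(x[i]))
        fixed[i] = (val, val)
    try:
        x_lp, obj_lp = solve_lp(
            c, A_eq=A_eq, b_eq=b_eq, A_ub=A_ub, b_ub=b_ub, bounds=fixed, maximize=maximize
        )
        if abs(obj_lp - claimed) <= tol:
            return x_lp, obj_lp
    except InfeasibleError:
        pass
    return _branch_and_bound(c, A_eq, b_eq, A_ub, b_ub, bounds, int_idx, maximize)


def _branch_and_bound(c, A_eq, b_eq, A_ub, b_ub, bounds, int_idx, maximize):
    """Exact depth-first branch-and-bound over 0/1 variables.

    Node relaxations are simplex LPs; a node only becomes an incumbent once
    every integer variable is hard-fixed (or its integral relaxation is
    reproduced exactly by a fully fixed LP), so solutions are exact up to LP
    tolerance.  Sized for the small extraction MILPs this package builds.
    """
    n = len(c)
    base_bounds = list(bounds) if bounds is not None else [(None, None)] * n
    better = (lambda a, b: a > b) if maximize else (lambda a, b: a < b)
    best: tuple[np.ndarray, float] | None = None

    def relax(fixed: dict):
        bl = list(base_bounds)
        for i, v in fixed.items():
            bl[i] = (v, v)
        return solve_lp(c, A_eq=A_eq, b_eq=b_eq, A_ub=A_ub, b_ub=b_ub,
                        bounds=bl, maximize=maximize)

    stack: list[dict] = [{}]
    guard = 0
    while stack:
        guard += 1
        if guard > 100000:
            raise OptimizationError("branch-and-bound node budget exceeded")
        fixed = stack.pop()
        try:
            x, val = relax(fixed)
        except InfeasibleError:
            continue
        tol = 1e-6 * max(1.0, abs(val))
        if best is not None and not better(val, best[1] + (tol if maximize else -tol)):
            continue
        free = [i for i in int_idx if i not in fixed]
        if not free:
            if best is None or better(val, best[1]):
                best = (x, val)
            continue
        fractional = [i for i in free if abs(x[i] - round(x[i])) > 1e-6]
        if not fractional:
            # integral relaxation: trust it only if a fully hard-fixed LP
            # reproduces the value (guards against big-M leakage)
            leaf = dict(fixed)
            for i in free:
                leaf[i] = float(round(x[i]))
            try:
                xe, ve = relax(leaf)
                if best is None or better(ve, best[1]):
                    best = (xe, ve)
                if abs(ve - val) <= tol:
                    continue
            except InfeasibleError:
                pass
            branch_var = free[0]
        else:
            branch_var = max(fractional, key=lambda i: abs(x[i] - round(x[i])))
        for v in (0.0, 1.0):
            child = dict(fixed)
            child[branch_var] = v
            stack.append(child)
    if best is None:
        raise InfeasibleError("MILP infeasible (exact branch-and-bound)")
    return best
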