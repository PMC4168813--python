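"""The iMAT-like family: similarity maximization without a required
functionality — iMAT match maximization, INIT weighted inclusion with net
metabolite production, and tINIT metabolic-task constraints.

iMAT classifies reactions into highly (R_H) and lowly (R_L) expressed groups
and solves a MILP maximizing the number of matches between reaction states
(active: |v| >= epsilon; inactive: v = 0) and data states.  Its adapted FVA
(:func:`imat_classify`) re-solves the MILP twice per reaction — once forcing
activity, once forcing inactivity — and labels the reaction active, inactive
or undetermined by comparing the two similarities.

INIT drops the grouping and instead weights a per-reaction inclusion binary
``y_i`` (``y_i = 1  <=>  |v_i| >= epsilon``) by a signed evidence score,
maximizing ``sum w_i y_i``; metabolites with experimental support must be
net-produced above ``delta``.  tINIT adds metabolic tasks the extracted model
must be able to perform and a direction binary per reversible reaction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._solver import InfeasibleError, solve_lp, solve_milp
from .flux_core import FluxDistribution, MetabolicModel, split_reversible

__all__ = [
    "MatchSpec",
    "InitSpec",
    "MetTask",
    "ImatResult",
    "InitResult",
    "TaskError",
    "imat",
    "imat_classify",
    "init",
    "tinit",
    "init_weights_from_expression",
]

EPSILON_DEFAULT = 1e-4


class TaskError(RuntimeError):
    """A metabolic task cannot be performed."""


@dataclass
class MatchSpec:
    """High/low expression groups and the activation flux for iMAT."""

    r_h: set[str]
    r_l: set[str]
    epsilon: float = EPSILON_DEFAULT

    def __post_init__(self):
        self.r_h, self.r_l = set(self.r_h), set(self.r_l)
        if self.r_h & self.r_l:
            raise ValueError(f"R_H and R_L overlap: {sorted(self.r_h & self.r_l)}")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


@dataclass
class MetTask:
    """A metabolic task: a linear combination of fluxes the retained submodel
    must be able to drive to at least ``lower`` (defaults to the spec delta)."""

    task_id: str
    coeffs: dict[str, float]
    lower: float | None = None


@dataclass
class InitSpec:
    """Weights, key metabolites and (for tINIT) tasks."""

    weights: dict[str, float] = field(default_factory=dict)
    key_metabolites: set[str] = field(default_factory=set)
    delta: float = 0.1
    tasks: list[MetTask] = field(default_factory=list)
    allow_net_production: bool = False
    steady_state: bool = False

    def __post_init__(self):
        if self.delta <= 0:
            raise ValueError("delta must be positive")


@dataclass
class ImatResult:
    objective: int
    flux: FluxDistribution
    r_p: set[str]


@dataclass
class InitResult:
    r_p: set[str]
    flux: FluxDistribution
    objective: float


# ---------------------------------------------------------------------------
# iMAT
# ---------------------------------------------------------------------------

def _imat_milp(model: MetabolicModel, spec: MatchSpec, bound_overrides=None):
    """Solve the iMAT MILP; returns (match_count, flux_values).

    Binaries reward |v_i| >= epsilon for i in R_H (one binary per feasible
    sense) and v_i = 0 for i in R_L; big-M coefficients come from the
    reaction's own bounds.
    """
    n = model.n_reactions
    lb = model.lb.copy()
    ub = model.ub.copy()
    for rid, (lo, hi) in (bound_overrides or {}).items():
        i = model.index(rid)
        lb[i], ub[i] = lo, hi
        if lo > hi:
            raise InfeasibleError(f"empty bound override for {rid}")
    eps = spec.epsilon
    unknown = (spec.r_h | spec.r_l) - set(model.reaction_ids)
    if unknown:
        raise KeyError(f"labelled reactions not in model: {sorted(unknown)}")

    binaries = []  # (kind, reaction index)
    for rid in sorted(spec.r_h):
        i = model.index(rid)
        binaries.append(("fwd", i))
        if lb[i] < 0:
            binaries.append(("rev", i))
    for rid in sorted(spec.r_l):
        binaries.append(("zero", model.index(rid)))
    n_y = len(binaries)
    ntot = n + n_y

    A_eq = np.hstack([model.S, np.zeros((model.n_metabolites, n_y))]) if model.n_metabolites else np.zeros((0, ntot))
    b_eq = np.zeros(A_eq.shape[0])
    rows, rhs = [], []
    for j, (kind, i) in enumerate(binaries):
        if kind == "fwd":
            # y=1 -> v_i >= eps :  -v_i + (eps - lb_i) y <= -lb_i
            row = np.zeros(ntot)
            row[i] = -1.0
            row[n + j] = eps - lb[i]
            rows.append(row)
            rhs.append(-lb[i])
        elif kind == "rev":
            # y=1 -> v_i <= -eps :  v_i + (eps + ub_i) y <= ub_i
            row = np.zeros(ntot)
            row[i] = 1.0
            row[n + j] = eps + ub[i]
            rows.append(row)
            rhs.append(ub[i])
        else:  # zero
            # y=1 -> v_i = 0
            row = np.zeros(ntot)
            row[i] = 1.0
            row[n + j] = ub[i]
            rows.append(row)
            rhs.append(ub[i])
            row = np.zeros(ntot)
            row[i] = -1.0
            row[n + j] = -lb[i]
            rows.append(row)
            rhs.append(-lb[i])
    c = np.zeros(ntot)
    c[n:] = 1.0
    bounds = [(float(lo), float(hi)) for lo, hi in zip(lb, ub)] + [(0.0, 1.0)] * n_y
    integrality = np.zeros(ntot)
    integrality[n:] = 1
    x, obj = solve_milp(
        c,
        A_eq=A_eq,
        b_eq=b_eq,
        A_ub=np.vstack(rows) if rows else None,
        b_ub=np.array(rhs) if rows else None,
        bounds=bounds,
        integrality=integrality,
        maximize=True,
    )
    return int(round(obj)), x[:n]


def imat(model: MetabolicModel, spec: MatchSpec) -> ImatResult:
    """Maximize the number of reactions whose flux state matches its
    expression group; the retained set is the incumbent's flux support."""
    objective, v = _imat_milp(model, spec)
    flux = FluxDistribution(list(model.reaction_ids), v, float(objective))
    r_p = {
        rid for rid, val in zip(model.reaction_ids, v) if abs(val) > spec.epsilon / 2
    }
    return ImatResult(objective, flux, r_p)


def imat_classify(model: MetabolicModel, spec: MatchSpec, reactions=None) -> dict[str, str]:
    """iMAT's adapted FVA: per reaction, compare the best similarity with the
    reaction forced active (s+) against forced inactive (s-).

    Labels: ``active`` (s+ > s-), ``inactive`` (s+ < s-), ``undetermined``
    (tie).  An infeasible forcing scores -inf, deciding the label by the
    other branch.
    """
    eps = spec.epsilon
    labels = {}
    for rid in reactions if reactions is not None else model.reaction_ids:
        i = model.index(rid)
        s_plus = -np.inf
        for lo, hi in ((eps, model.ub[i]), (model.lb[i], -eps)):
            if lo > hi:
                continue
            try:
                score, _ = _imat_milp(model, spec, {rid: (lo, hi)})
            except InfeasibleError:
                continue
            s_plus = max(s_plus, score)
        try:
            s_minus, _ = _imat_milp(model, spec, {rid: (0.0, 0.0)})
        except InfeasibleError:
            s_minus = -np.inf
        if s_plus > s_minus:
            labels[rid] = "active"
        elif s_plus < s_minus:
            labels[rid] = "inactive"
        else:
            labels[rid] = "undetermined"
    return labels


# ---------------------------------------------------------------------------
# INIT / tINIT
# ---------------------------------------------------------------------------

def init_weights_from_expression(reaction_data: dict[str, float], threshold: float) -> dict[str, float]:
    """Convenience weight builder: signed log2 ratio of evidence to threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    floor = 1e-9
    return {rid: float(np.log2(max(d, floor) / threshold)) for rid, d in reaction_data.items()}


def _check_key_production(model, key_metabolites, delta, relaxed):
    """Verify each key metabolite can be net-produced above delta; error naming
    the first that cannot."""
    for m in key_metabolites:
        j = model.met_index(m)
        n = model.n_reactions
        rows, rhs_lo = [], []
        A_eq_rows = []
        for jj in range(model.n_metabolites):
            if jj == j:
                continue
            if relaxed:
                rows.append(-model.S[jj, :])  # S_m' v >= 0
                rhs_lo.append(0.0)
            else:
                A_eq_rows.append(model.S[jj, :])
        A_eq = np.vstack(A_eq_rows) if A_eq_rows else None
        b_eq = np.zeros(len(A_eq_rows)) if A_eq_rows else None
        A_ub = np.vstack(rows) if rows else None
        b_ub = np.array(rhs_lo) if rows else None
        try:
            _, best = solve_lp(
                model.S[j, :], A_eq=A_eq, b_eq=b_eq, A_ub=A_ub, b_ub=b_ub,
                bounds=model.bounds_list(), maximize=True,
            )
        except InfeasibleError as exc:
            raise InfeasibleError(f"key metabolite {m!r} cannot be produced: {exc}") from exc
        if best < delta:
            raise InfeasibleError(
                f"key metabolite {m!r}: maximal net production {best:.6g} < delta {delta}"
            )


def _init_milp(model: MetabolicModel, spec: InitSpec, epsilon: float, tasks: list[MetTask]):
    """Shared INIT/tINIT MILP builder.

    Variables: split fluxes, one inclusion binary per original reaction, one
    direction binary per reversible reaction (so forward and reverse senses
    cannot both run and |v| equals the split-flux sum), and per task an
    auxiliary steady-state flux vector confined to the retained reactions.
    """
    split, mapping = split_reversible(model)
    idx = {rid: i for i, rid in enumerate(split.reaction_ids)}
    n_v = split.n_reactions
    n_r = model.n_reactions
    rev_ids = sorted(mapping.reverse)
    n_d = len(rev_ids)
    n_t = len(tasks)
    ntot = n_v + n_r + n_d + n_t * n_v

    def u_off(t):
        return n_v + n_r + n_d + t * n_v

    big_m = np.maximum(np.abs(model.lb), np.abs(model.ub))
    weights = np.array([float(spec.weights.get(r, 0.0)) for r in model.reaction_ids])
    c = np.zeros(ntot)
    c[n_v : n_v + n_r] = weights

    bounds = split.bounds_list() + [(0.0, 1.0)] * (n_r + n_d)
    for _ in range(n_t):
        bounds += [(0.0, hi) for (_, hi) in split.bounds_list()]

    key = set(spec.key_metabolites)
    unknown_mets = key - set(model.metabolite_ids)
    if unknown_mets:
        raise KeyError(f"unknown key metabolites: {sorted(unknown_mets)}")

    A_eq_rows, b_eq = [], []
    A_ub_rows, b_ub = [], []

    # mass balance for the main flux vector: b_m >= delta for key metabolites,
    # b_m = 0 (or >= 0 in relaxed mode) otherwise; steady-state mode zeroes all
    for j, m in enumerate(model.metabolite_ids):
        row = np.zeros(ntot)
        row[:n_v] = split.S[j, :]
        if not spec.steady_state and m in key:
            A_ub_rows.append(-row)
            b_ub.append(-spec.delta)
        elif not spec.steady_state and spec.allow_net_production:
            A_ub_rows.append(-row)
            b_ub.append(0.0)
        else:
            A_eq_rows.append(row)
            b_eq.append(0.0)

    # activity coupling: a_i = v_for + v_rev ;  eps*y <= a <= M*y
    for i, rid in enumerate(model.reaction_ids):
        cols = [idx[mapping.forward[rid]]]
        if rid in mapping.reverse:
            cols.append(idx[mapping.reverse[rid]])
        row = np.zeros(ntot)
        for col in cols:
            row[col] = -1.0
        row[n_v + i] = epsilon
        A_ub_rows.append(row)  # eps*y - a <= 0
        b_ub.append(0.0)
        row = np.zeros(ntot)
        for col in cols:
            row[col] = 1.0
        row[n_v + i] = -float(big_m[i]) if big_m[i] > 0 else -1.0
        A_ub_rows.append(row)  # a - M*y <= 0
        b_ub.append(0.0)

    def _direction_rows(offset, d_col_of):
        """One-direction coupling for a flux block starting at ``offset``."""
        for jd, rid in enumerate(rev_ids):
            fcol = idx[mapping.forward[rid]]
            rcol = idx[mapping.reverse[rid]]
            row = np.zeros(ntot)
            row[offset + fcol] = 1.0
            row[d_col_of(jd)] = -float(split.ub[fcol])
            A_ub_rows.append(row)  # v_for <= ub_for * d
            b_ub.append(0.0)
            row = np.zeros(ntot)
            row[offset + rcol] = 1.0
            row[d_col_of(jd)] = float(split.ub[rcol])
            A_ub_rows.append(row)  # v_rev <= ub_rev * (1 - d)
            b_ub.append(float(split.ub[rcol]))

    _direction_rows(0, lambda jd: n_v + n_r + jd)

    # task blocks: steady-state auxiliary flux confined to retained reactions
    for t, task in enumerate(tasks):
        off = u_off(t)
        for j in range(model.n_metabolites):
            row = np.zeros(ntot)
            row[off : off + n_v] = split.S[j, :]
            A_eq_rows.append(row)
            b_eq.append(0.0)
        for i, rid in enumerate(model.reaction_ids):
            cols = [idx[mapping.forward[rid]]]
            if rid in mapping.reverse:
                cols.append(idx[mapping.reverse[rid]])
            for col in cols:
                row = np.zeros(ntot)
                row[off + col] = 1.0
                row[n_v + i] = -float(split.ub[col])
                A_ub_rows.append(row)  # u <= ub * y_i
                b_ub.append(0.0)
        _direction_rows(off, lambda jd: n_v + n_r + jd)
        lower = task.lower if task.lower is not None else spec.delta
        row = np.zeros(ntot)
        for rid, coef in task.coeffs.items():
            row[off + idx[mapping.forward[rid]]] += float(coef)
            if rid in mapping.reverse:
                row[off + idx[mapping.reverse[rid]]] -= float(coef)
        A_ub_rows.append(-row)
        b_ub.append(-float(lower))

    integrality = np.zeros(ntot)
    integrality[n_v : n_v + n_r + n_d] = 1
    x, obj = solve_milp(
        c,
        A_eq=np.vstack(A_eq_rows) if A_eq_rows else None,
        b_eq=np.array(b_eq) if A_eq_rows else None,
        A_ub=np.vstack(A_ub_rows) if A_ub_rows else None,
        b_ub=np.array(b_ub) if A_ub_rows else None,
        bounds=bounds,
        integrality=integrality,
        maximize=True,
    )
    merged = mapping.merge(split, x[:n_v])
    values = np.array([merged[r] for r in model.reaction_ids])
    y = x[n_v : n_v + n_r]
    r_p = {rid for i, rid in enumerate(model.reaction_ids) if y[i] > 0.5}
    return InitResult(r_p, FluxDistribution(list(model.reaction_ids), values, obj), float(obj))


def init(model: MetabolicModel, spec: InitSpec, *, epsilon: float = EPSILON_DEFAULT) -> InitResult:
    """INIT: maximize the summed weight of included reactions, forcing net
    production of key metabolites above ``delta``."""
    if spec.weights and all(w < 0 for w in spec.weights.values()) and not spec.key_metabolites:
        warnings.warn("all weights are negative: the extracted set may be empty", stacklevel=2)
    if not spec.steady_state and spec.key_metabolites:
        _check_key_production(model, spec.key_metabolites, spec.delta, spec.allow_net_production)
    return _init_milp(model, spec, epsilon, tasks=[])


def tinit(model: MetabolicModel, spec: InitSpec, *, epsilon: float = EPSILON_DEFAULT,
          drop_infeasible_tasks: bool = False) -> InitResult:
    """tINIT: INIT plus metabolic-task constraints.

    Every task is first checked for feasibility in the generic model (error
    listing the task otherwise).  Tasks that are individually feasible but
    incompatible with the data-driven optimum make the joint MILP infeasible;
    with ``drop_infeasible_tasks`` they are reported and dropped one by one.
    """
    tasks = list(spec.tasks)
    for task in tasks:
        unknown = set(task.coeffs) - set(model.reaction_ids)
        if unknown:
            raise TaskError(
                f"task {task.task_id!r} names reactions absent from the model: {sorted(unknown)}"
            )
        lower = task.lower if task.lower is not None else spec.delta
        row = {rid: float(c) for rid, c in task.coeffs.items()}
        try:
            from .flux_core import fba

            best = fba(model, row).objective_value
        except InfeasibleError as exc:
            raise TaskError(f"task {task.task_id!r} infeasible in the generic model") from exc
        if best < lower:
            raise TaskError(
                f"task {task.task_id!r} infeasible in the generic model: "
                f"max {best:.6g} < required {lower}"
            )
    if not spec.steady_state and spec.key_metabolites:
        _check_key_production(model, spec.key_metabolites, spec.delta, spec.allow_net_production)
    while True:
        try:
            return _init_milp(model, spec, epsilon, tasks=tasks)
        except InfeasibleError:
            if not (drop_infeasible_tasks and tasks):
                raise
            dropped = tasks.pop()
            warnings.warn(f"task {dropped.task_id!r} incompatible with the data; dropped", stacklevel=2)
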