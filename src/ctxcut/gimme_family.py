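"""The GIMME-like family: extraction maximizing similarity to data subject to
a Required Metabolic Functionality (RMF).

Both members solve the same two-step problem.  Step one computes the RMF
optimum by FBA; step two minimizes the inconsistency score

    IS = sum_i p_i * |v_i|

over the steady-state polytope with the operability constraint
``RMF(v) >= k * RMF_opt``, ``k in [0, 1]``.  GIMME penalizes only reactions
whose mapped expression falls below the user threshold and stays an LP
(|v| realized by reversible splitting).  GIM3E penalizes every reaction by
its GPR-mapped distance to the sample maximum, forces sink flux for
metabolites with evidence of synthesis (``v_sink >= epsilon``), and restricts
each reversible reaction to a single direction through one binary variable,
turning the problem into a MILP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._solver import InfeasibleError, solve_lp, solve_milp
from .flux_core import (
    DEFAULT_BOUND,
    FluxDistribution,
    MetabolicModel,
    fba,
    split_reversible,
)

__all__ = [
    "RmfError",
    "RmfSpec",
    "GimmeResult",
    "gimme",
    "gim3e",
    "add_metabolite_sinks",
]

EPSILON_DEFAULT = 1e-4


class RmfError(RuntimeError):
    """The required metabolic functionality cannot be achieved."""


@dataclass
class RmfSpec:
    """A required metabolic functionality: a flux objective and the fraction
    ``k`` of its FBA optimum the extracted model must sustain."""

    objective: object  # reaction id, {id: coef} or coefficient vector
    k: float = 0.9

    def __post_init__(self):
        if not (0.0 <= self.k <= 1.0):
            raise ValueError(f"k must lie in [0, 1], got {self.k}")


@dataclass
class GimmeResult:
    """Outcome of a GIMME-like extraction."""

    r_p: set[str]
    flux: FluxDistribution
    inconsistency_score: float
    rmf_opt: float
    rmf_value: float
    classification: dict[str, str] = field(default_factory=dict)


def _split_system(model: MetabolicModel):
    """Split model plus index bookkeeping for |v| objectives."""
    split, mapping = split_reversible(model)
    idx = {rid: i for i, rid in enumerate(split.reaction_ids)}
    # per original reaction: list of split-variable indices whose sum is |v|
    abs_vars = {}
    for orig in model.reaction_ids:
        cols = [idx[mapping.forward[orig]]]
        if orig in mapping.reverse:
            cols.append(idx[mapping.reverse[orig]])
        abs_vars[orig] = cols
    return split, mapping, idx, abs_vars


def _rmf_row(model, mapping, idx, n, rmf_vec):
    """RMF expression as a row over split variables."""
    row = np.zeros(n)
    for i, rid in enumerate(model.reaction_ids):
        coef = float(rmf_vec[i])
        if coef == 0:
            continue
        row[idx[mapping.forward[rid]]] += coef
        if rid in mapping.reverse:
            row[idx[mapping.reverse[rid]]] -= coef
    return row


def _rmf_opt(model: MetabolicModel, rmf: RmfSpec) -> tuple[np.ndarray, float]:
    rmf_vec = model.objective_vector(rmf.objective)
    sol = fba(model, rmf_vec)
    if sol.objective_value <= 0:
        raise RmfError(
            f"RMF cannot be achieved: FBA optimum is {sol.objective_value:.6g}"
        )
    return rmf_vec, sol.objective_value


def gimme(
    model: MetabolicModel,
    penalty: dict[str, float],
    rmf: RmfSpec,
    *,
    expressed: set[str] | None = None,
    epsilon: float = EPSILON_DEFAULT,
) -> GimmeResult:
    """GIMME: minimize the inconsistency score subject to the RMF constraint.

    ``penalty`` comes from :func:`ctxcut.gpr.gimme_penalty`.  ``expressed``
    is the above-threshold reaction set {i : d_i >= c}; when omitted it is
    approximated as the zero-penalty reactions.  The retained set is
    ``expressed ∪ {i : |v_i| > epsilon}``.
    """
    rmf_vec, rmf_opt = _rmf_opt(model, rmf)
    split, mapping, idx, abs_vars = _split_system(model)
    n = split.n_reactions
    c = np.zeros(n)
    for orig, cols in abs_vars.items():
        p = float(penalty.get(orig, 0.0))
        for col in cols:
            c[col] += p
    A_eq = split.S if split.n_metabolites else np.zeros((0, n))
    b_eq = np.zeros(A_eq.shape[0])
    rmf_row = _rmf_row(model, mapping, idx, n, rmf_vec)
    A_ub = -rmf_row[None, :]
    b_ub = np.array([-rmf.k * rmf_opt])
    x, is_score = solve_lp(
        c, A_eq=A_eq, b_eq=b_eq, A_ub=A_ub, b_ub=b_ub, bounds=split.bounds_list()
    )
    merged = mapping.merge(split, x)
    values = np.array([merged[r] for r in model.reaction_ids])
    flux = FluxDistribution(list(model.reaction_ids), values, is_score)
    rmf_value = float(rmf_vec @ values)
    if expressed is None:
        expressed = {rid for rid, p in penalty.items() if p == 0.0}
    carrying = {r for r, v in merged.items() if abs(v) > epsilon}
    r_p = (set(expressed) & set(model.reaction_ids)) | carrying
    classification = {
        r: ("expressed" if r in expressed else "flux-carrying" if r in carrying else "excluded")
        for r in model.reaction_ids
    }
    return GimmeResult(r_p, flux, is_score, rmf_opt, rmf_value, classification)


def gim3e(
    model: MetabolicModel,
    penalty: dict[str, float],
    rmf: RmfSpec,
    key_met_sinks=(),
    *,
    epsilon: float = EPSILON_DEFAULT,
    fva_widen: bool = False,
) -> GimmeResult:
    """GIM3E: penalty minimization with key-metabolite sink activation and
    one direction binary per reversible reaction (a MILP).

    ``penalty`` comes from :func:`ctxcut.gpr.gim3e_penalty`; ``key_met_sinks``
    are sink reaction ids (see :func:`add_metabolite_sinks`) forced to carry
    at least ``epsilon`` flux.  The retained set is
    ``{i : |v_i| > epsilon/2} ∪ key_met_sinks``, optionally widened by FVA
    under the penalty-optimum constraint.
    """
    key_met_sinks = list(key_met_sinks)
    for sink in key_met_sinks:
        model.index(sink)  # raises on unknown id
    rmf_vec, rmf_opt = _rmf_opt(model, rmf)
    split, mapping, idx, abs_vars = _split_system(model)
    n_v = split.n_reactions
    rev_ids = sorted(mapping.reverse)  # originals with a reverse sense
    n_y = len(rev_ids)
    n = n_v + n_y

    c = np.zeros(n)
    for orig, cols in abs_vars.items():
        p = float(penalty.get(orig, 0.0))
        for col in cols:
            c[col] += p

    bounds = split.bounds_list() + [(0.0, 1.0)] * n_y
    for sink in key_met_sinks:
        col = idx[mapping.forward[sink]]
        lo, hi = bounds[col]
        bounds[col] = (max(lo, epsilon), hi)

    A_eq = np.hstack([split.S, np.zeros((split.n_metabolites, n_y))])
    b_eq = np.zeros(A_eq.shape[0])

    A_ub_rows, b_ub = [], []
    rmf_row = np.zeros(n)
    rmf_row[:n_v] = _rmf_row(model, mapping, idx, n_v, rmf_vec)
    A_ub_rows.append(-rmf_row)
    b_ub.append(-rmf.k * rmf_opt)
    # direction binaries: y = 1 selects the forward sense, y = 0 the reverse
    for j, orig in enumerate(rev_ids):
        fcol, rcol = idx[mapping.forward[orig]], idx[mapping.reverse[orig]]
        f_ub = split.ub[fcol]
        r_ub = split.ub[rcol]
        row = np.zeros(n)
        row[fcol] = 1.0
        row[n_v + j] = -f_ub
        A_ub_rows.append(row)  # v_for <= ub_for * y
        b_ub.append(0.0)
        row = np.zeros(n)
        row[rcol] = 1.0
        row[n_v + j] = r_ub
        A_ub_rows.append(row)  # v_rev <= ub_rev * (1 - y)
        b_ub.append(r_ub)

    integrality = np.zeros(n)
    integrality[n_v:] = 1
    try:
        x, is_score = solve_milp(
            c,
            A_eq=A_eq,
            b_eq=b_eq,
            A_ub=np.vstack(A_ub_rows),
            b_ub=np.array(b_ub),
            bounds=bounds,
            integrality=integrality,
        )
    except InfeasibleError:
        _diagnose_sinks(model, key_met_sinks, epsilon)
        raise
    merged = mapping.merge(split, x[:n_v])
    values = np.array([merged[r] for r in model.reaction_ids])
    flux = FluxDistribution(list(model.reaction_ids), values, is_score)
    rmf_value = float(rmf_vec @ values)
    r_p = {r for r, v in merged.items() if abs(v) > epsilon / 2} | set(key_met_sinks)
    if fva_widen:
        r_p |= _fva_widen(
            model, penalty, rmf_vec, rmf.k * rmf_opt, is_score, epsilon
        )
    classification = {
        r: ("sink" if r in key_met_sinks else "flux-carrying" if r in r_p else "excluded")
        for r in model.reaction_ids
    }
    return GimmeResult(r_p, flux, is_score, rmf_opt, rmf_value, classification)


def _diagnose_sinks(model, key_met_sinks, epsilon):
    """Name the metabolite whose sink cannot reach epsilon flux."""
    from .flux_core import fva

    for sink in key_met_sinks:
        try:
            rng = fva(model, [sink])
        except InfeasibleError:
            continue
        if rng[sink][1] < epsilon:
            met = _sink_metabolite(model, sink)
            raise InfeasibleError(
                f"key metabolite {met!r}: sink {sink!r} cannot carry flux >= {epsilon}"
            )


def _sink_metabolite(model, sink_id):
    col = model.S[:, model.index(sink_id)]
    nz = np.where(col != 0)[0]
    return model.metabolite_ids[nz[0]] if nz.size else "?"


def _fva_widen(model, penalty, rmf_vec, rmf_min, is_opt, epsilon):
    """Reactions able to carry >= epsilon flux at the penalty optimum."""
    split, mapping, idx, abs_vars = _split_system(model)
    n = split.n_reactions
    pen_row = np.zeros(n)
    for orig, cols in abs_vars.items():
        for col in cols:
            pen_row[col] += float(penalty.get(orig, 0.0))
    A_eq = split.S if split.n_metabolites else np.zeros((0, n))
    b_eq = np.zeros(A_eq.shape[0])
    rmf_row = _rmf_row(model, mapping, idx, n, rmf_vec)
    A_ub = np.vstack([-rmf_row, pen_row])
    b_ub = np.array([-rmf_min, is_opt + 1e-6])
    widened = set()
    for orig, cols in abs_vars.items():
        c = np.zeros(n)
        for col in cols:
            c[col] = 1.0
        try:
            _, best = solve_lp(
                c, A_eq=A_eq, b_eq=b_eq, A_ub=A_ub, b_ub=b_ub,
                bounds=split.bounds_list(), maximize=True,
            )
        except InfeasibleError:
            continue
        if best >= epsilon:
            widened.add(orig)
    return widened


def add_metabolite_sinks(
    model: MetabolicModel, key_metabolites
) -> tuple[MetabolicModel, dict[str, str]]:
    """Ensure each key metabolite has an irreversible sink ``m ->``; returns
    the augmented model and a ``{metabolite: sink_reaction_id}`` mapping.

    Existing sinks are reused, so the operation is idempotent.
    """
    key_metabolites = list(key_metabolites)
    for m in key_metabolites:
        model.met_index(m)  # raises on unknown id
    out = model.copy()
    sinks: dict[str, str] = {}
    for m in key_metabolites:
        j = out.met_index(m)
        existing = None
        for i, rid in enumerate(out.reaction_ids):
            col = out.S[:, i]
            nz = np.where(col != 0)[0]
            if nz.size == 1 and nz[0] == j and col[j] < 0 and out.ub[i] > 0 and out.lb[i] >= 0:
                existing = rid
                break
        if existing is not None:
            sinks[m] = existing
            continue
        sink_id = f"SK_{m}"
        suffix = 0
        while sink_id in out.reaction_ids:
            suffix += 1
            sink_id = f"SK_{m}_{suffix}"
        col = np.zeros((out.n_metabolites, 1))
        col[j, 0] = -1.0
        out = MetabolicModel(
            out.reaction_ids + [sink_id],
            list(out.metabolite_ids),
            np.hstack([out.S, col]),
            np.append(out.lb, 0.0),
            np.append(out.ub, DEFAULT_BOUND),
            dict(out.gpr),
            None if out.objective is None else np.append(out.objective, 0.0),
        )
        sinks[m] = sink_id
    return out, sinks
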