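import itertools

import numpy as np
import pytest

from ctxcut import MetabolicModel, fba
from ctxcut._solver import InfeasibleError, solve_lp


def build_model(reactions, gpr=None, objective=None):
    """Compact model builder: reactions = [(id, {met: coef}, lb, ub), ...]."""
    mets: list[str] = []
    for _, stoich, _, _ in reactions:
        for m in stoich:
            if m not in mets:
                mets.append(m)
    S = np.zeros((len(mets), len(reactions)))
    for i, (_, stoich, _, _) in enumerate(reactions):
        for m, coef in stoich.items():
            S[mets.index(m), i] = coef
    return MetabolicModel(
        [r[0] for r in reactions],
        mets,
        S,
        np.array([r[2] for r in reactions], float),
        np.array([r[3] for r in reactions], float),
        gpr or {},
        objective,
    )


@pytest.fixture
def chain():
    """r1: -> A, r2: A -> B, r3: B ->, all bounded 0..10."""
    return build_model(
        [
            ("r1", {"A": 1}, 0, 10),
            ("r2", {"A": -1, "B": 1}, 0, 10),
            ("r3", {"B": -1}, 0, 10),
        ]
    )


@pytest.fixture
def chain_deadend():
    """Chain plus r4: A -> C with C never consumed (r4 is blocked)."""
    return build_model(
        [
            ("r1", {"A": 1}, 0, 10),
            ("r2", {"A": -1, "B": 1}, 0, 10),
            ("r3", {"B": -1}, 0, 10),
            ("r4", {"A": -1, "C": 1}, 0, 10),
        ]
    )


@pytest.fixture
def parallel_path():
    """r1: -> A; r2, r3: A -> B (parallel); r4: B ->, all bounded 0..10."""
    return build_model(
        [
            ("r1", {"A": 1}, 0, 10),
            ("r2", {"A": -1, "B": 1}, 0, 10),
            ("r3", {"A": -1, "B": 1}, 0, 10),
            ("r4", {"B": -1}, 0, 10),
        ]
    )


def enumerate_gim3e_optimum(model, penalty, rmf, sinks=(), epsilon=1e-4):
    """Independent GIM3E oracle: exhaust both fixings of every reversible
    reaction and solve the resulting penalty-minimization LP directly.

    The RMF optimum is computed once on the unrestricted model, exactly as
    the MILP does.  Returns the best (minimal) inconsistency score, or None
    when every fixing is infeasible.
    """
    rmf_vec = model.objective_vector(rmf.objective)
    rmf_opt = fba(model, rmf_vec).objective_value
    rev = sorted(model.reversible)
    best = None
    for mask in itertools.product((0, 1), repeat=len(rev)):
        m2 = model.copy()
        for rid, bit in zip(rev, mask):
            i = m2.index(rid)
            if bit:
                m2.lb[i] = 0.0  # forward sense
            else:
                m2.ub[i] = 0.0  # reverse sense
        bounds = m2.bounds_list()
        for sink in sinks:
            i = m2.index(sink)
            lo, hi = bounds[i]
            bounds[i] = (max(lo, epsilon), hi)
        # after fixing, |v_i| is v_i (lb >= 0) or -v_i (ub <= 0)
        c = np.zeros(m2.n_reactions)
        for i, rid in enumerate(m2.reaction_ids):
            p = float(penalty.get(rid, 0.0))
            c[i] = p if bounds[i][0] >= 0 else -p
        A_ub = -rmf_vec[None, :]
        b_ub = np.array([-rmf.k * rmf_opt])
        try:
            _, obj = solve_lp(
                c, A_eq=m2.S, b_eq=np.zeros(m2.n_metabolites),
                A_ub=A_ub, b_ub=b_ub, bounds=bounds,
            )
        except InfeasibleError:
            continue
        if best is None or obj < best:
            best = obj
    return best
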