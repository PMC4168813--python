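"""The MBA-like family: consistency-driven pruning.

These methods only extract a model — no flux prediction.  Reactions are
categorized a priori into a core (positive evidence of activity) and a
non-core; the generic model is then pruned so that the result contains the
core and has no blocked reaction (flux consistency, the family's defining
objective).

Members:

* :func:`mba` / :func:`mba_single` — randomized elimination over a seeded
  permutation of the non-core, with a two-tier core (high / moderate
  likelihood) and a population-ranking consolidation step;
* :func:`mcadre` — score-ranked pruning (expression, connectivity,
  confidence) with key-metabolite protection and a relaxation that lets
  negative-evidence reactions sacrifice part of the core;
* :func:`fastcore` — sparse-mode expansion: two LPs per round
  (:func:`find_sparse_mode`) grow a minimal consistent superset of the core,
  flipping reversible reactions that resist activation.

Two fast consistency checkers are provided alongside
:func:`~ctxcut.flux_core.find_blocked_fva` (the exact reference):
:func:`check_model_consistency_mba` (iterated flux-sum maximization with an
FVA fallback) and :func:`check_model_consistency_fastcore` (the sparse-mode
sweep).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._solver import InfeasibleError, solve_lp
from .flux_core import (
    BLOCKED_TOL,
    MetabolicModel,
    extract_submodel,
    find_blocked_fva,
    flip_reaction,
    fva,
)
from .gpr import parse_gpr

__all__ = [
    "CoreSpec",
    "McadreScores",
    "ConsistencyError",
    "check_model_consistency_mba",
    "check_model_consistency_fastcore",
    "mba_single",
    "mba",
    "mcadre_scores",
    "mcadre",
    "binarize_expression",
    "find_sparse_mode",
    "fastcore",
]

EPSILON_DEFAULT = 1e-4
#: support-extraction tolerance for sparse modes, two orders below epsilon
FLUX_TOL_FACTOR = 1e-2


class ConsistencyError(RuntimeError):
    """A core reaction is blocked where the method requires it unblocked."""


@dataclass
class CoreSpec:
    """Two-tier core for MBA: high-likelihood (curated) and moderate-
    likelihood (data-driven) reactions, plus optional negative evidence,
    key-metabolite producers and the ratio parameter k."""

    c_h: set[str]
    c_m: set[str] = field(default_factory=set)
    negative: set[str] = field(default_factory=set)
    key_met_prod: set[str] = field(default_factory=set)
    k: float = 0.5

    def __post_init__(self):
        self.c_h, self.c_m = set(self.c_h), set(self.c_m)
        self.negative = set(self.negative)
        self.key_met_prod = set(self.key_met_prod)
        if self.c_h & self.c_m:
            raise ValueError(f"C_H and C_M overlap: {sorted(self.c_h & self.c_m)}")
        if self.negative & self.c_h:
            raise ValueError(
                f"negative evidence conflicts with high-likelihood core: {sorted(self.negative & self.c_h)}"
            )

    @property
    def core(self) -> set[str]:
        return self.c_h | self.c_m


# ---------------------------------------------------------------------------
# Consistency checkers
# ---------------------------------------------------------------------------

def check_model_consistency_mba(
    model: MetabolicModel,
    *,
    epsilon: float = EPSILON_DEFAULT,
    seed: int = 0,
) -> set[str]:
    """MBA's fast blocked-reaction detector.

    Iteratively maximizes the total flux over the still-unresolved reactions,
    then minimizes it over the unresolved reversibles so both senses are
    explored; reactions reaching ``epsilon`` net flux are unblocked.  When an
    iteration resolves nothing, one randomly chosen unresolved reaction is
    settled by FVA.  Agrees with :func:`find_blocked_fva` on the supported
    model class.
    """
    if model.n_reactions == 0:
        return set()
    rng = np.random.default_rng(seed)
    idx = {rid: i for i, rid in enumerate(model.reaction_ids)}
    rev = model.reversible
    A_eq = model.S if model.n_metabolites else np.zeros((0, model.n_reactions))
    b_eq = np.zeros(A_eq.shape[0])
    bounds = model.bounds_list()
    unresolved = set(model.reaction_ids)
    blocked: set[str] = set()
    while unresolved:
        # first LP: maximize the total flux over unresolved reactions;
        # second LP: minimize it over the unresolved reversibles (their
        # reverse senses).  Working with net fluxes, never split senses,
        # so a futile forward+reverse pair cannot fake activity.
        newly: set[str] = set()
        for maximize, members in (
            (True, unresolved),
            (False, unresolved & rev),
        ):
            if not members:
                continue
            c = np.zeros(model.n_reactions)
            for orig in members:
                c[idx[orig]] = 1.0
            x, _ = solve_lp(c, A_eq=A_eq, b_eq=b_eq, bounds=bounds, maximize=maximize)
            newly |= {orig for orig in unresolved if abs(x[idx[orig]]) >= epsilon}
        if newly:
            unresolved -= newly
            continue
        rid = sorted(unresolved)[rng.integers(len(unresolved))]
        lo, hi = fva(model, [rid])[rid]
        if abs(lo) <= BLOCKED_TOL and abs(hi) <= BLOCKED_TOL:
            blocked.add(rid)
        unresolved.discard(rid)
    return blocked


def _lp7(model: MetabolicModel, J, epsilon: float) -> np.ndarray:
    """Cardinality-maximization LP: maximize sum of z_i, z_i in [0, eps],
    v_i >= z_i for i in J; returns the flux vector."""
    n = model.n_reactions
    J = [model.index(r) for r in J]
    nz = len(J)
    ntot = n + nz
    c = np.zeros(ntot)
    c[n:] = 1.0
    A_eq = np.hstack([model.S, np.zeros((model.n_metabolites, nz))]) if model.n_metabolites else np.zeros((0, ntot))
    b_eq = np.zeros(A_eq.shape[0])
    rows = []
    for j, i in enumerate(J):
        row = np.zeros(ntot)
        row[n + j] = 1.0
        row[i] = -1.0
        rows.append(row)  # z_i - v_i <= 0
    bounds = model.bounds_list() + [(0.0, epsilon)] * nz
    x, _ = solve_lp(
        c, A_eq=A_eq, b_eq=b_eq,
        A_ub=np.vstack(rows) if rows else None,
        b_ub=np.zeros(len(rows)) if rows else None,
        bounds=bounds, maximize=True,
    )
    return x[:n]


def check_model_consistency_fastcore(
    model: MetabolicModel, *, epsilon: float = EPSILON_DEFAULT
) -> set[str]:
    """Sparse-mode sweep consistency checker (the FastCORE-style "fastcc"
    routine): LP-based activation with reversible-sense flipping; reactions
    that resist every orientation are blocked."""
    if model.n_reactions == 0:
        return set()
    current = model.copy()
    all_ids = set(model.reaction_ids)
    irrev = {rid for rid, lo in zip(model.reaction_ids, model.lb) if lo >= 0}
    tol = 0.99 * epsilon

    def supp(v):
        return {rid for rid, val in zip(current.reaction_ids, v) if abs(val) >= tol}

    J = sorted(all_ids & irrev)
    A = supp(_lp7(current, J, epsilon))
    blocked = set(J) - A
    J = all_ids - A - blocked
    flipped = False
    singleton = False
    while J:
        Ji = {sorted(J)[0]} if singleton else set(J)
        A |= supp(_lp7(current, sorted(Ji), epsilon))
        if J & A:
            J -= A
            flipped = False
        else:
            ji_rev = Ji - irrev
            if flipped or not ji_rev:
                flipped = False
                if singleton:
                    blocked |= Ji
                    J -= Ji
                else:
                    singleton = True
            else:
                for rid in sorted(ji_rev):
                    current = flip_reaction(current, rid)
                flipped = True
    return blocked


# ---------------------------------------------------------------------------
# MBA
# ---------------------------------------------------------------------------

def _blocked_in(model: MetabolicModel, keep) -> set[str]:
    return find_blocked_fva(extract_submodel(model, keep))


def mba_single(model: MetabolicModel, core: CoreSpec, permutation) -> set[str]:
    """One randomized MBA elimination pass over the given non-core order.

    A tentative removal of ``r`` is committed — together with the moderate-
    core and non-core reactions it blocks — only when no high-likelihood core
    reaction becomes blocked and the moderate-core damage stays below
    ``k`` times the non-core collateral (removals that block nothing are
    always committed).
    """
    ids = set(model.reaction_ids)
    unknown = (core.core | set(permutation)) - ids
    if unknown:
        raise KeyError(f"unknown reactions: {sorted(unknown)}")
    if find_blocked_fva(model) & core.c_h:
        raise ConsistencyError("high-likelihood core is blocked in generic model")
    n_c = ids - core.core
    if set(permutation) != n_c:
        raise ValueError("permutation must order exactly the non-core reactions")
    r_p = set(ids)
    for r in permutation:
        if r not in r_p:
            continue
        tentative = r_p - {r}
        blocked = _blocked_in(model, tentative)
        e_h = blocked & core.c_h
        e_m = blocked & core.c_m
        e_nc = blocked - core.core
        if not e_h and (not e_m or len(e_m) < core.k * len(e_nc)):
            r_p = tentative - e_m - e_nc
    return r_p


def mba(
    model: MetabolicModel,
    core: CoreSpec,
    n_iter: int = 1000,
    seed: int = 0,
) -> tuple[set[str], list[tuple[str, float]]]:
    """Population MBA: repeat the randomized elimination over ``n_iter``
    seeded permutations, rank reactions outside the high-likelihood core by
    their occurrence frequency, then rebuild a consistent model by adding
    ranked reactions to C_H until the core is unblocked.

    Returns the final flux-consistent retained set and the ranking table
    (reaction id, occurrence frequency), deterministic under ``seed``.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if find_blocked_fva(model) & core.c_h:
        raise ConsistencyError("high-likelihood core is blocked in generic model")
    rng = np.random.default_rng(seed)
    n_c = sorted(set(model.reaction_ids) - core.core)
    counts: dict[str, int] = {rid: 0 for rid in model.reaction_ids if rid not in core.c_h}
    for _ in range(n_iter):
        perm = [n_c[i] for i in rng.permutation(len(n_c))]
        r_p = mba_single(model, core, perm)
        for rid in r_p:
            if rid in counts:
                counts[rid] += 1
    ranking = sorted(
        ((rid, cnt / n_iter) for rid, cnt in counts.items()),
        key=lambda item: (-item[1], item[0]),
    )
    kept = set(core.c_h)
    queue = [rid for rid, _ in ranking]
    blocked = _blocked_in(model, kept)
    while blocked & core.c_h if core.c_h else blocked:
        if not queue:
            break
        kept.add(queue.pop(0))
        blocked = _blocked_in(model, kept)
    # prune any remaining blocked non-C_H reactions; removing a blocked
    # reaction cannot block others, so one pass suffices
    final = kept - (_blocked_in(model, kept) - core.c_h)
    return final, ranking


# ---------------------------------------------------------------------------
# mCADRE
# ---------------------------------------------------------------------------

@dataclass
class McadreScores:
    """Per-reaction expression frequency, neighborhood connectivity and
    evidence confidence used to rank reactions for mCADRE."""

    expression: dict[str, float]
    connectivity: dict[str, float]
    confidence: dict[str, float]
    has_evidence: set[str] = field(default_factory=set)


def binarize_expression(profiles: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Convenience thresholder: samples x genes intensities -> 0/1 states."""
    return (profiles >= threshold).astype(int)


def mcadre_scores(
    model: MetabolicModel,
    binarized_profiles: pd.DataFrame,
    confidence: dict[str, float] | None = None,
) -> McadreScores:
    """Score reactions from binarized expression profiles (samples x genes).

    The expression score is the frequency of the GPR-mapped expressed state
    across samples; the connectivity score is the mean expression score of
    reactions sharing a metabolite; the confidence score is passed through
    (0 = no evidence).
    """
    if binarized_profiles.shape[0] < 1:
        raise ValueError("at least one expression profile is required")
    values = binarized_profiles.to_numpy()
    if not np.isin(values, (0, 1)).all():
        raise ValueError(
            "profiles must be binarized to 0/1 states first (see binarize_expression)"
        )
    expression: dict[str, float] = {}
    has_evidence: set[str] = set()
    rules = {rid: parse_gpr(text) for rid, text in model.gpr.items()}
    for rid in model.reaction_ids:
        rule = rules.get(rid)
        if rule is None:
            expression[rid] = 0.0
            continue
        states = []
        for _, sample in binarized_profiles.iterrows():
            state = rule.evaluate(sample.to_dict(), and_op=min, or_op=max)
            if state is not None:
                states.append(float(state))
        if states:
            expression[rid] = float(np.mean(states))
            has_evidence.add(rid)
        else:
            expression[rid] = 0.0
    nz = model.S != 0
    connectivity: dict[str, float] = {}
    for i, rid in enumerate(model.reaction_ids):
        shared = np.any(nz[nz[:, i], :], axis=0)
        neighbors = [
            model.reaction_ids[j] for j in np.where(shared)[0] if j != i
        ]
        connectivity[rid] = (
            float(np.mean([expression[r] for r in neighbors])) if neighbors else 0.0
        )
    conf = {rid: float((confidence or {}).get(rid, 0.0)) for rid in model.reaction_ids}
    return McadreScores(expression, connectivity, conf, has_evidence)


def _can_produce(model: MetabolicModel, metabolite: str, delta: float) -> bool:
    """Can the model sustain net production of ``metabolite`` above delta?"""
    j = model.met_index(metabolite)
    others = [jj for jj in range(model.n_metabolites) if jj != j]
    A_eq = model.S[others, :] if others else None
    b_eq = np.zeros(len(others)) if others else None
    try:
        _, best = solve_lp(
            model.S[j, :], A_eq=A_eq, b_eq=b_eq, bounds=model.bounds_list(), maximize=True
        )
    except InfeasibleError:
        return False
    return best >= delta


def mcadre(
    model: MetabolicModel,
    scores: McadreScores,
    core_threshold: float = 0.5,
    key_metabolites=(),
    k: float = 0.33,
    *,
    epsilon: float = EPSILON_DEFAULT,
) -> set[str]:
    """mCADRE: score-ranked pruning with core relaxation.

    The core is ``{expression_score >= core_threshold}``; reactions with
    expression evidence but an all-zero expressed state carry negative
    evidence.  Non-core reactions are removed in ascending score order.  A
    removal must never impair key-metabolite production nor (for reactions
    without negative evidence) block any core reaction; negative-evidence
    reactions may sacrifice core reactions as long as the blocked-core count
    stays below ``k`` times the blocked non-core count.
    """
    key_metabolites = list(key_metabolites)
    for m in key_metabolites:
        if not _can_produce(model, m, epsilon):
            raise InfeasibleError(
                f"key metabolite {m!r} cannot be produced in the generic model"
            )
    # start from the consistent part of the generic model
    r_p = set(model.reaction_ids) - find_blocked_fva(model)
    core = {rid for rid in r_p if scores.expression.get(rid, 0.0) >= core_threshold}
    negative = {
        rid for rid in r_p
        if rid in scores.has_evidence and scores.expression.get(rid, 0.0) == 0.0
    }
    key_met_prod = set()
    for m in key_metabolites:
        j = model.met_index(m)
        for i, rid in enumerate(model.reaction_ids):
            coef = model.S[j, i]
            if coef > 0 or (coef < 0 and model.lb[i] < 0):
                key_met_prod.add(rid)
    order = sorted(
        (rid for rid in r_p if rid not in core),
        key=lambda rid: (
            scores.expression.get(rid, 0.0),
            scores.connectivity.get(rid, 0.0),
            scores.confidence.get(rid, 0.0),
            rid,
        ),
    )
    for r in order:
        if r not in r_p:
            continue
        tentative = r_p - {r}
        sub = extract_submodel(model, tentative)
        blocked = find_blocked_fva(sub)
        e_c = blocked & core
        e_met = blocked & key_met_prod
        e_nc = blocked - core
        if e_met:
            continue
        # key-metabolite production must survive the removal itself
        if key_metabolites:
            after = extract_submodel(model, tentative - e_nc - (e_c if r in negative else set()))
            if not all(
                m in after.metabolite_ids and _can_produce(after, m, epsilon)
                for m in key_metabolites
            ):
                continue
        if r not in negative:
            if not e_c:
                r_p = tentative - e_nc
        else:
            if not e_c or len(e_c) < k * len(e_nc):
                r_p = tentative - e_nc - e_c
    return r_p


# ---------------------------------------------------------------------------
# FastCORE
# ---------------------------------------------------------------------------

def find_sparse_mode(
    model: MetabolicModel,
    J,
    P,
    epsilon: float = EPSILON_DEFAULT,
) -> set[str]:
    """FastCORE's two-LP sparse mode.

    LP1 maximizes the number of ``J`` reactions driven to at least
    ``epsilon`` flux (cardinality via auxiliary ``z_i in [0, epsilon]``);
    LP2 then minimizes the L1-norm of the flux over the penalized set ``P``
    while keeping the activated core ``K`` at flux >= epsilon.  Returns the
    support of the LP2 solution (empty when nothing in ``J`` can be
    activated).
    """
    J, P = list(J), list(P)
    if set(J) & set(P):
        raise ValueError("J and P must be disjoint")
    if not J:
        return set()
    v1 = _lp7(model, J, epsilon)
    idx = {rid: i for i, rid in enumerate(model.reaction_ids)}
    K = [rid for rid in J if v1[idx[rid]] >= 0.99 * epsilon]
    if not K:
        return set()
    n = model.n_reactions
    nz = len(P)
    ntot = n + nz
    c = np.zeros(ntot)
    c[n:] = 1.0
    A_eq = np.hstack([model.S, np.zeros((model.n_metabolites, nz))]) if model.n_metabolites else np.zeros((0, ntot))
    b_eq = np.zeros(A_eq.shape[0])
    rows, rhs = [], []
    for j, rid in enumerate(P):
        i = idx[rid]
        row = np.zeros(ntot)
        row[i] = 1.0
        row[n + j] = -1.0
        rows.append(row)  # v - z <= 0
        rhs.append(0.0)
        row = np.zeros(ntot)
        row[i] = -1.0
        row[n + j] = -1.0
        rows.append(row)  # -v - z <= 0
        rhs.append(0.0)
    bounds = model.bounds_list() + [(0.0, None)] * nz
    for rid in K:
        i = idx[rid]
        lo, hi = bounds[i]
        bounds[i] = (max(lo, epsilon), hi)
    x, _ = solve_lp(
        c, A_eq=A_eq, b_eq=b_eq,
        A_ub=np.vstack(rows) if rows else None,
        b_ub=np.array(rhs) if rows else None,
        bounds=bounds,
    )
    flux_tol = FLUX_TOL_FACTOR * epsilon
    return {rid for rid, val in zip(model.reaction_ids, x[:n]) if abs(val) > flux_tol}


def fastcore(
    model: MetabolicModel,
    core,
    epsilon: float = EPSILON_DEFAULT,
) -> set[str]:
    """FastCORE: grow a minimal flux-consistent superset of the core.

    The model is first reduced to its consistent part; a core reaction
    blocked in the generic model is an error.  Sparse modes are then added
    in alternating fashion, flipping the sign of reversible core reactions
    that resist forward activation.
    """
    core = set(core)
    unknown = core - set(model.reaction_ids)
    if unknown:
        raise KeyError(f"core reactions not in model: {sorted(unknown)}")
    blocked0 = find_blocked_fva(model)
    bad = core & blocked0
    if bad:
        raise ConsistencyError(f"core reactions blocked in the generic model: {sorted(bad)}")
    work = extract_submodel(model, set(model.reaction_ids) - blocked0)
    irrev = {rid for rid, lo in zip(work.reaction_ids, work.lb) if lo >= 0}
    non_core = set(work.reaction_ids) - core
    current = work.copy()

    flux_tol = FLUX_TOL_FACTOR * epsilon
    J = sorted(core & irrev)
    A = find_sparse_mode(current, J, sorted(non_core), epsilon)
    if set(J) - A:
        raise ConsistencyError(
            f"irreversible core reactions could not be activated: {sorted(set(J) - A)}"
        )
    J = core - A
    flipped = False
    singleton = False
    while J:
        P = sorted(non_core - A)
        Ji = {sorted(J)[0]} if singleton else set(J)
        A |= find_sparse_mode(current, sorted(Ji), P, epsilon)
        if J & A:
            J -= A
            flipped = False
        else:
            ji_rev = Ji - irrev
            if flipped or not ji_rev:
                if singleton:
                    raise ConsistencyError(
                        f"cannot activate core reaction(s): {sorted(Ji)}"
                    )
                flipped = False
                singleton = True
            else:
                for rid in sorted(ji_rev):
                    current = flip_reaction(current, rid)
                flipped = True
    return A
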