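"""Toy-model and evidence generators with known ground truth, plus exact
brute-force oracles.

The generated networks are deliberately small and structured — a linear
pathway fed by an uptake reaction and drained by an export, optional
parallel routes around its middle step, and dead-end branches whose products
are never consumed.  The dead ends are the exact blocked set, and the chain
plus its exchanges form a flux-consistent "context" that the extraction
methods should recover from matching evidence.

Evidence emulates a two-population intensity model on a log-like scale:
genes of context-active reactions draw from Normal(8, sd), inactive ones
from Normal(2, sd), truncated at zero; binary profiles threshold at the
midpoint 5.  With sd = 0 the separation is perfect, isolating algorithmic
behaviour from noise; the noise level is a :class:`ToySpec` choice, not a
biological claim.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._solver import InfeasibleError, solve_lp
from .flux_core import (
    DEFAULT_BOUND,
    MetabolicModel,
    extract_submodel,
    find_blocked_fva,
)

__all__ = [
    "SizeError",
    "ToySpec",
    "GroundTruth",
    "make_toy_model",
    "make_random_model",
    "make_evidence",
    "brute_force_consistent_subsets",
    "brute_force_min_consistent_supersets",
    "brute_force_imat",
]

HIGH_MEAN = 8.0
LOW_MEAN = 2.0
BINARY_THRESHOLD = 5.0


class SizeError(ValueError):
    """Problem too large for exhaustive enumeration."""


@dataclass
class ToySpec:
    """Shape of a generated toy network."""

    n_linear: int = 3
    n_parallel: int = 0
    n_deadends: int = 0
    reversible_fraction: float = 0.0
    seed: int = 0
    composite_gpr: bool = False

    def __post_init__(self):
        if min(self.n_linear, self.n_parallel, self.n_deadends) < 0:
            raise ValueError("counts must be >= 0")
        if not (0.0 <= self.reversible_fraction <= 1.0):
            raise ValueError("reversible_fraction must lie in [0, 1]")


@dataclass
class GroundTruth:
    """The simulated context: which reactions are truly active, which are
    structurally blocked, and a suggested core for pruning methods."""

    active_set: set[str]
    blocked_set: set[str]
    core_suggestion: set[str] = field(default_factory=set)


def _gpr_for(rid: str, composite: bool, rng) -> str:
    if not composite:
        return f"g_{rid}"
    if rng.random() < 0.5:
        return f"gA_{rid} and gB_{rid}"
    return f"gA_{rid} or gB_{rid}"


def make_toy_model(spec: ToySpec) -> tuple[MetabolicModel, GroundTruth]:
    """Build the chain/parallel/dead-end toy network described above.

    Deterministic under ``spec.seed``.  A degenerate all-zero spec yields a
    minimal one-reaction exchange model (whose sole reaction is blocked at
    steady state, with an empty active set).
    """
    rng = np.random.default_rng(spec.seed)
    if spec.n_linear == 0:
        model = MetabolicModel(
            ["EX_X"], ["X"], np.array([[-1.0]]), np.array([0.0]), np.array([DEFAULT_BOUND]),
            {"EX_X": _gpr_for("EX_X", spec.composite_gpr, rng)},
        )
        return model, GroundTruth(set(), {"EX_X"}, set())
    n = spec.n_linear
    mets = [f"M{i}" for i in range(n + 1)]
    reactions = []  # (id, stoich, lb, ub)
    reactions.append(("EX_in", {"M0": 1.0}, 0.0, DEFAULT_BOUND))
    chain = []
    for i in range(1, n + 1):
        rid = f"R{i}"
        chain.append(rid)
        reactions.append((rid, {mets[i - 1]: -1.0, mets[i]: 1.0}, 0.0, DEFAULT_BOUND))
    mid = (n + 1) // 2
    parallel = []
    for j in range(1, spec.n_parallel + 1):
        rid = f"P{j}"
        parallel.append(rid)
        reactions.append((rid, {mets[mid - 1]: -1.0, mets[mid]: 1.0}, 0.0, DEFAULT_BOUND))
    deadends = []
    for j in range(1, spec.n_deadends + 1):
        rid = f"D{j}"
        deadends.append(rid)
        src = mets[(j - 1) % n]
        mets.append(f"X{j}")
        reactions.append((rid, {src: -1.0, f"X{j}": 1.0}, 0.0, DEFAULT_BOUND))
    reactions.append(("EX_out", {mets[n]: -1.0}, 0.0, DEFAULT_BOUND))

    internal = chain + parallel + deadends
    n_rev = int(round(spec.reversible_fraction * len(internal)))
    rev_pick = set(
        np.array(internal)[rng.choice(len(internal), size=n_rev, replace=False)]
    ) if n_rev else set()

    rids = [r[0] for r in reactions]
    S = np.zeros((len(mets), len(rids)))
    met_idx = {m: i for i, m in enumerate(mets)}
    lb, ub = [], []
    for i, (rid, stoich, lo, hi) in enumerate(reactions):
        for m, coef in stoich.items():
            S[met_idx[m], i] = coef
        lb.append(-DEFAULT_BOUND if rid in rev_pick else lo)
        ub.append(hi)
    gpr = {rid: _gpr_for(rid, spec.composite_gpr, rng) for rid in rids}
    model = MetabolicModel(rids, mets, S, np.array(lb), np.array(ub), gpr)
    active = set(chain) | {"EX_in", "EX_out"}
    truth = GroundTruth(active, set(deadends), set(chain))
    return model, truth


def make_random_model(
    n_reactions: int = 12,
    seed: int = 0,
    reversible_fraction: float = 0.3,
) -> MetabolicModel:
    """A seeded random 1-to-1 conversion network with one uptake and one
    export; dead ends and disconnected pockets arise naturally, giving a mix
    of blocked and unblocked reactions."""
    if n_reactions < 3:
        raise ValueError("need at least 3 reactions")
    rng = np.random.default_rng(seed)
    n_mets = max(2, n_reactions // 2)
    mets = [f"m{j}" for j in range(n_mets)]
    reactions = [("up", {mets[0]: 1.0}, 0.0), ("ex", {mets[-1]: -1.0}, 0.0)]
    for i in range(n_reactions - 2):
        src, dst = rng.choice(n_mets, size=2, replace=False)
        lo = -DEFAULT_BOUND if rng.random() < reversible_fraction else 0.0
        reactions.append((f"r{i+1}", {mets[src]: -1.0, mets[dst]: 1.0}, lo))
    rids = [r[0] for r in reactions]
    S = np.zeros((n_mets, len(rids)))
    met_idx = {m: j for j, m in enumerate(mets)}
    lb = []
    for i, (rid, stoich, lo) in enumerate(reactions):
        for m, coef in stoich.items():
            S[met_idx[m], i] = coef
        lb.append(lo)
    return MetabolicModel(
        rids, mets, S, np.array(lb), np.full(len(rids), DEFAULT_BOUND)
    )


def make_evidence(
    model: MetabolicModel,
    truth: GroundTruth,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_samples: int = 4,
) -> tuple[dict[str, float], pd.DataFrame]:
    """Draw gene intensities and per-sample binary profiles for the context.

    Genes of active reactions draw from Normal(HIGH_MEAN, sd), others from
    Normal(LOW_MEAN, sd), truncated at 0; profiles threshold each sample's
    redraw at the midpoint.  Deterministic under ``seed``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    from .gpr import parse_gpr

    rng = np.random.default_rng(seed)
    gene_active: dict[str, bool] = {}
    for rid, text in model.gpr.items():
        rule = parse_gpr(text)
        if rule is None:
            continue
        for g in sorted(rule.genes()):
            gene_active[g] = rid in truth.active_set
    genes = sorted(gene_active)
    means = np.array([HIGH_MEAN if gene_active[g] else LOW_MEAN for g in genes])
    values = np.maximum(0.0, rng.normal(means, noise_sd))
    gene_values = {g: float(v) for g, v in zip(genes, values)}
    draws = np.maximum(0.0, rng.normal(means[None, :], noise_sd, size=(n_samples, len(genes))))
    profiles = pd.DataFrame(
        (draws >= BINARY_THRESHOLD).astype(int), columns=genes,
        index=[f"s{i+1}" for i in range(n_samples)],
    )
    return gene_values, profiles


# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------

def brute_force_consistent_subsets(
    model: MetabolicModel, must_keep=()
) -> tuple[list[set[str]], list[set[str]]]:
    """Enumerate every flux-consistent reaction subset containing
    ``must_keep``; returns (all such subsets, the minimum-cardinality ones).

    Exact but exponential; refuses models beyond 14 reactions.
    """
    if model.n_reactions > 14:
        raise SizeError("exhaustive enumeration capped at 14 reactions")
    must_keep = set(must_keep)
    unknown = must_keep - set(model.reaction_ids)
    if unknown:
        raise KeyError(f"unknown reactions: {sorted(unknown)}")
    free = sorted(set(model.reaction_ids) - must_keep)
    consistent: list[set[str]] = []
    for r in range(len(free) + 1):
        for combo in itertools.combinations(free, r):
            subset = must_keep | set(combo)
            if not find_blocked_fva(extract_submodel(model, subset)):
                consistent.append(subset)
    if not consistent:
        return [], []
    min_size = min(len(s) for s in consistent)
    return consistent, [s for s in consistent if len(s) == min_size]


def brute_force_min_consistent_supersets(
    model: MetabolicModel, must_keep=()
) -> tuple[int | None, list[set[str]]]:
    """Minimum-cardinality flux-consistent supersets of ``must_keep`` via
    ascending-cardinality search (stops at the first feasible size)."""
    if model.n_reactions > 14:
        raise SizeError("exhaustive enumeration capped at 14 reactions")
    must_keep = set(must_keep)
    free = sorted(set(model.reaction_ids) - must_keep)
    for r in range(len(free) + 1):
        minima = []
        for combo in itertools.combinations(free, r):
            subset = must_keep | set(combo)
            if not find_blocked_fva(extract_submodel(model, subset)):
                minima.append(subset)
        if minima:
            return len(must_keep) + r, minima
    return None, []


def _pattern_feasible(model: MetabolicModel, assignment: dict[str, tuple[float, float]]) -> bool:
    bounds = model.bounds_list()
    for rid, (lo, hi) in assignment.items():
        i = model.index(rid)
        b_lo, b_hi = bounds[i]
        lo, hi = max(lo, b_lo), min(hi, b_hi)
        if lo > hi:
            return False
        bounds[i] = (lo, hi)
    A_eq = model.S if model.n_metabolites else None
    b_eq = np.zeros(model.n_metabolites) if model.n_metabolites else None
    try:
        solve_lp(np.zeros(model.n_reactions), A_eq=A_eq, b_eq=b_eq, bounds=bounds)
    except InfeasibleError:
        return False
    return True


def brute_force_imat(model: MetabolicModel, spec) -> int:
    """Exact iMAT objective by enumerating satisfied subsets of R_H ∪ R_L
    (largest first), checking each activity pattern with one feasibility LP.

    A satisfied highly-expressed reaction must carry |v| >= epsilon in some
    sense; a satisfied lowly-expressed reaction must be silent (v = 0).
    """
    labelled = sorted(spec.r_h | spec.r_l)
    if len(labelled) > 10:
        raise SizeError("iMAT enumeration capped at 10 labelled reactions")
    eps = spec.epsilon
    for size in range(len(labelled), -1, -1):
        for satisfied in itertools.combinations(labelled, size):
            sat_h = [r for r in satisfied if r in spec.r_h]
            sat_l = [r for r in satisfied if r in spec.r_l]
            sense_choices = []
            for rid in sat_h:
                i = model.index(rid)
                options = []
                if model.ub[i] >= eps:
                    options.append((eps, np.inf))
                if model.lb[i] <= -eps:
                    options.append((-np.inf, -eps))
                if not options:
                    break
                sense_choices.append(options)
            else:
                for senses in itertools.product(*sense_choices):
                    assignment = {rid: rng for rid, rng in zip(sat_h, senses)}
                    assignment.update({rid: (0.0, 0.0) for rid in sat_l})
                    if _pattern_feasible(model, assignment):
                        return size
    return 0
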