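"""Metabolic model representation, I/O, and shared flux-analysis machinery.

The central object is :class:`MetabolicModel`: a stoichiometric matrix ``S``
(metabolites x reactions), per-reaction flux bounds, optional gene-protein-
reaction (GPR) rule strings and an optional linear objective.  On top of it sit
the operations every extraction method needs:

* :func:`fba` — flux balance analysis (maximize a linear flux objective over
  the steady-state polytope ``S.v = 0``, ``v_min <= v <= v_max``);
* :func:`fva` — flux variability analysis (per-reaction min/max flux);
* :func:`find_blocked_fva` — the reference blocked-reaction detector, against
  which the two heuristic consistency checkers in :mod:`ctxcut.mba_family`
  are validated;
* :func:`split_reversible`, :func:`flip_reaction`, :func:`extract_submodel` —
  the structural transformations the methods are built from.

Models are read and written in SBML Level 3 (via cobrapy/libSBML) or in a
small documented JSON dialect::

    {
      "metabolites": ["A", "B"],
      "reactions": [
        {"id": "r1", "stoich": {"A": 1.0}, "lb": 0, "ub": 1000, "gpr": "g1"},
        ...
      ],
      "objective": {"r3": 1.0}          # optional
    }

Bounds default to +/-1000 flux units when a file omits them, the common
genome-scale convention.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._solver import InfeasibleError, OptimizationError, UnboundedError, solve_lp

__all__ = [
    "DEFAULT_BOUND",
    "ZERO_TOL",
    "BLOCKED_TOL",
    "ValidationError",
    "FormatError",
    "MetabolicModel",
    "FluxDistribution",
    "FvaResult",
    "load_model",
    "save_model",
    "fba",
    "fva",
    "find_blocked_fva",
    "split_reversible",
    "flip_reaction",
    "extract_submodel",
]

#: Default flux bound magnitude when a file omits bounds.
DEFAULT_BOUND = 1000.0
#: Numerical zero at the solver level.
ZERO_TOL = 1e-9
#: A reaction is classified blocked when its FVA interval lies within
#: ``[-BLOCKED_TOL, BLOCKED_TOL]`` — one order below the activation threshold
#: epsilon = 1e-4 used by the extraction methods, to avoid boundary flapping.
BLOCKED_TOL = 1e-6


class ValidationError(ValueError):
    """Model violates a structural invariant (duplicate ids, bad bounds...)."""


class FormatError(ValueError):
    """A model file does not parse under the named standard."""


@dataclass
class MetabolicModel:
    """A constraint-based metabolic model.

    ``S`` has one row per metabolite and one column per reaction; a positive
    coefficient means the reaction produces the metabolite.  ``gpr`` maps a
    reaction id to its boolean gene rule text (reactions without a rule are
    simply absent from the mapping).
    """

    reaction_ids: list[str]
    metabolite_ids: list[str]
    S: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    gpr: dict[str, str] = field(default_factory=dict)
    objective: np.ndarray | None = None

    def __post_init__(self):
        self.S = np.asarray(self.S, dtype=float)
        self.lb = np.asarray(self.lb, dtype=float)
        self.ub = np.asarray(self.ub, dtype=float)
        n_met, n_rxn = len(self.metabolite_ids), len(self.reaction_ids)
        if self.S.shape != (n_met, n_rxn):
            raise ValidationError(
                f"S shape {self.S.shape} != (metabolites={n_met}, reactions={n_rxn})"
            )
        if len(set(self.reaction_ids)) != n_rxn:
            dups = sorted({r for r in self.reaction_ids if self.reaction_ids.count(r) > 1})
            raise ValidationError(f"duplicate reaction identifiers: {dups}")
        if len(set(self.metabolite_ids)) != n_met:
            dups = sorted({m for m in self.metabolite_ids if self.metabolite_ids.count(m) > 1})
            raise ValidationError(f"duplicate metabolite identifiers: {dups}")
        if self.lb.shape != (n_rxn,) or self.ub.shape != (n_rxn,):
            raise ValidationError("bound vectors must have one entry per reaction")
        if np.any(self.lb > self.ub):
            bad = [self.reaction_ids[i] for i in np.where(self.lb > self.ub)[0]]
            raise ValidationError(f"lb > ub for reactions: {bad}")
        if n_met and n_rxn:
            empty = [self.reaction_ids[i] for i in range(n_rxn) if not np.any(self.S[:, i])]
            if empty:
                raise ValidationError(f"reactions with all-zero stoichiometry: {empty}")
        if self.objective is not None:
            self.objective = np.asarray(self.objective, dtype=float)
            if self.objective.shape != (n_rxn,):
                raise ValidationError("objective length must equal the reaction count")
        unknown_gpr = set(self.gpr) - set(self.reaction_ids)
        if unknown_gpr:
            raise ValidationError(f"GPR rules for unknown reactions: {sorted(unknown_gpr)}")

    # -- basic queries ----------------------------------------------------

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    def index(self, reaction_id: str) -> int:
        try:
            return self.reaction_ids.index(reaction_id)
        except ValueError:
            raise KeyError(f"unknown reaction id: {reaction_id!r}") from None

    def met_index(self, metabolite_id: str) -> int:
        try:
            return self.metabolite_ids.index(metabolite_id)
        except ValueError:
            raise KeyError(f"unknown metabolite id: {metabolite_id!r}") from None

    @property
    def reversible(self) -> set[str]:
        """Rev: reactions with v_min < 0 < v_max."""
        return {
            rid
            for rid, lo, hi in zip(self.reaction_ids, self.lb, self.ub)
            if lo < 0 < hi
        }

    def is_exchange(self, reaction_id: str) -> bool:
        """Structural exchange/sink test: a single non-zero stoichiometric entry."""
        col = self.S[:, self.index(reaction_id)]
        return int(np.count_nonzero(col)) == 1

    def objective_vector(self, objective=None) -> np.ndarray:
        """Resolve an objective given as vector, dict or reaction id."""
        if objective is None:
            if self.objective is None:
                raise ValidationError("model has no objective and none was given")
            return self.objective
        if isinstance(objective, str):
            c = np.zeros(self.n_reactions)
            c[self.index(objective)] = 1.0
            return c
        if isinstance(objective, dict):
            c = np.zeros(self.n_reactions)
            for rid, coef in objective.items():
                c[self.index(rid)] = float(coef)
            return c
        c = np.asarray(objective, dtype=float)
        if c.shape != (self.n_reactions,):
            raise ValidationError("objective length must equal the reaction count")
        return c

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            reaction_ids=list(self.reaction_ids),
            metabolite_ids=list(self.metabolite_ids),
            S=self.S.copy(),
            lb=self.lb.copy(),
            ub=self.ub.copy(),
            gpr=dict(self.gpr),
            objective=None if self.objective is None else self.objective.copy(),
        )

    def bounds_list(self) -> list[tuple[float, float]]:
        return [(float(lo), float(hi)) for lo, hi in zip(self.lb, self.ub)]


@dataclass
class FluxDistribution:
    """A steady-state flux vector in the model's reaction order."""

    reaction_ids: list[str]
    values: np.ndarray
    objective_value: float

    def __getitem__(self, reaction_id: str) -> float:
        return float(self.values[self.reaction_ids.index(reaction_id)])

    def as_dict(self) -> dict[str, float]:
        return {r: float(v) for r, v in zip(self.reaction_ids, self.values)}

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("reaction_id\tflux\n")
            for r, v in zip(self.reaction_ids, self.values):
                fh.write(f"{r}\t{v:.10g}\n")


@dataclass
class FvaResult:
    """Per-reaction flux ranges from flux variability analysis."""

    ranges: dict[str, tuple[float, float]]

    def __getitem__(self, reaction_id: str) -> tuple[float, float]:
        return self.ranges[reaction_id]

    def blocked(self, tol: float = BLOCKED_TOL) -> set[str]:
        return {
            rid
            for rid, (lo, hi) in self.ranges.items()
            if abs(lo) <= tol and abs(hi) <= tol
        }


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _from_json_dict(doc: dict) -> MetabolicModel:
    if "reactions" not in doc or "metabolites" not in doc:
        raise FormatError("JSON model must contain 'metabolites' and 'reactions'")
    metabolite_ids = list(doc["metabolites"])
    reaction_ids: list[str] = []
    gpr: dict[str, str] = {}
    n_met = len(metabolite_ids)
    cols, lbs, ubs = [], [], []
    met_index = {m: i for i, m in enumerate(metabolite_ids)}
    if len(met_index) != n_met:
        raise ValidationError("duplicate metabolite identifiers in JSON model")
    for rxn in doc["reactions"]:
        rid = rxn["id"]
        if rid in reaction_ids:
            raise ValidationError(f"reaction {rid!r} listed twice")
        reaction_ids.append(rid)
        col = np.zeros(n_met)
        for met, coef in rxn.get("stoich", {}).items():
            if met not in met_index:
                raise FormatError(f"reaction {rid!r} references unknown metabolite {met!r}")
            col[met_index[met]] = float(coef)
        cols.append(col)
        lbs.append(float(rxn.get("lb", -DEFAULT_BOUND)))
        ubs.append(float(rxn.get("ub", DEFAULT_BOUND)))
        rule = rxn.get("gpr", "")
        if rule:
            gpr[rid] = rule
    S = np.column_stack(cols) if cols else np.zeros((n_met, 0))
    objective = None
    if doc.get("objective"):
        objective = np.zeros(len(reaction_ids))
        for rid, coef in doc["objective"].items():
            if rid not in reaction_ids:
                raise FormatError(f"objective references unknown reaction {rid!r}")
            objective[reaction_ids.index(rid)] = float(coef)
    return MetabolicModel(reaction_ids, metabolite_ids, S, np.array(lbs), np.array(ubs), gpr, objective)


def _to_json_dict(model: MetabolicModel) -> dict:
    reactions = []
    for i, rid in enumerate(model.reaction_ids):
        stoich = {
            model.metabolite_ids[j]: float(model.S[j, i])
            for j in np.where(model.S[:, i] != 0)[0]
        }
        entry = {"id": rid, "stoich": stoich, "lb": float(model.lb[i]), "ub": float(model.ub[i])}
        if rid in model.gpr:
            entry["gpr"] = model.gpr[rid]
        reactions.append(entry)
    doc = {"metabolites": list(model.metabolite_ids), "reactions": reactions}
    if model.objective is not None:
        doc["objective"] = {
            model.reaction_ids[i]: float(c)
            for i, c in enumerate(model.objective)
            if c != 0
        }
    return doc


def _from_cobra(cmodel) -> MetabolicModel:
    metabolite_ids = [m.id for m in cmodel.metabolites]
    reaction_ids = [r.id for r in cmodel.reactions]
    met_index = {m: i for i, m in enumerate(metabolite_ids)}
    S = np.zeros((len(metabolite_ids), len(reaction_ids)))
    lbs, ubs = [], []
    gpr = {}
    for i, r in enumerate(cmodel.reactions):
        for met, coef in r.metabolites.items():
            S[met_index[met.id], i] = float(coef)
        lbs.append(float(r.lower_bound))
        ubs.append(float(r.upper_bound))
        if r.gene_reaction_rule:
            gpr[r.id] = r.gene_reaction_rule
    objective = None
    coefs = {r.id: c for r, c in _cobra_objective_coeffs(cmodel).items()}
    if any(c != 0 for c in coefs.values()):
        objective = np.zeros(len(reaction_ids))
        for rid, c in coefs.items():
            objective[reaction_ids.index(rid)] = c
    return MetabolicModel(reaction_ids, metabolite_ids, S, np.array(lbs), np.array(ubs), gpr, objective)


def _cobra_objective_coeffs(cmodel):
    from cobra.util.solver import linear_reaction_coefficients

    return linear_reaction_coefficients(cmodel)


def to_cobra(model: MetabolicModel):
    """Convert to a cobrapy model (used for SBML I/O and as an FBA cross-check)."""
    import cobra

    cmodel = cobra.Model("ctxcut_model")
    mets = {}
    for m in model.metabolite_ids:
        cm = cobra.Metabolite(m, compartment="c")
        mets[m] = cm
    cmodel.add_metabolites(list(mets.values()))
    rxns = []
    for i, rid in enumerate(model.reaction_ids):
        cr = cobra.Reaction(rid)
        cr.lower_bound = float(model.lb[i])
        cr.upper_bound = float(model.ub[i])
        rxns.append(cr)
    cmodel.add_reactions(rxns)
    for i, rid in enumerate(model.reaction_ids):
        cr = cmodel.reactions.get_by_id(rid)
        cr.add_metabolites(
            {mets[model.metabolite_ids[j]]: float(model.S[j, i]) for j in np.where(model.S[:, i] != 0)[0]}
        )
        if rid in model.gpr:
            cr.gene_reaction_rule = model.gpr[rid]
    if model.objective is not None:
        cmodel.objective = {
            cmodel.reactions.get_by_id(model.reaction_ids[i]): float(c)
            for i, c in enumerate(model.objective)
            if c != 0
        }
    return cmodel


def load_model(path, format: str | None = None) -> MetabolicModel:
    """Load a model from SBML Level 3 or the JSON dialect documented above.

    ``format`` is inferred from the suffix (.xml/.sbml vs .json) when omitted.
    """
    path = Path(path)
    if format is None:
        format = "sbml" if path.suffix.lower() in {".xml", ".sbml"} else "json"
    if format == "json":
        try:
            with open(path) as fh:
                doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"unparsable JSON model {path}: {exc}") from exc
        return _from_json_dict(doc)
    if format == "sbml":
        from cobra.io import read_sbml_model

        try:
            cmodel = read_sbml_model(str(path))
        except Exception as exc:  # libsbml raises a zoo of error types
            raise FormatError(f"unparsable SBML model {path}: {exc}") from exc
        return _from_cobra(cmodel)
    raise ValueError(f"unknown model format: {format!r}")


def save_model(model: MetabolicModel, path, format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "sbml" if path.suffix.lower() in {".xml", ".sbml"} else "json"
    if format == "json":
        with open(path, "w") as fh:
            json.dump(_to_json_dict(model), fh, indent=1, sort_keys=True)
            fh.write("\n")
    elif format == "sbml":
        from cobra.io import write_sbml_model

        write_sbml_model(to_cobra(model), str(path))
    else:
        raise ValueError(f"unknown model format: {format!r}")


# ---------------------------------------------------------------------------
# LP machinery
# ---------------------------------------------------------------------------

def _steady_state_system(model: MetabolicModel, extra_constraints=None):
    """Assemble (A_eq, b_eq, A_ub, b_ub, bounds) for the flux polytope.

    ``extra_constraints`` is an iterable of ``(coeffs, lo, hi)`` with ``coeffs``
    a ``{reaction_id: coefficient}`` mapping; ``lo``/``hi`` may be ``None``.
    """
    n = model.n_reactions
    A_eq = model.S if model.n_metabolites else np.zeros((0, n))
    b_eq = np.zeros(A_eq.shape[0])
    A_ub_rows, b_ub = [], []
    eq_rows, eq_rhs = [A_eq], [b_eq]
    for coeffs, lo, hi in extra_constraints or ():
        row = np.zeros(n)
        for rid, coef in coeffs.items():
            row[model.index(rid)] = float(coef)
        if lo is not None and hi is not None and lo == hi:
            eq_rows.append(row[None, :])
            eq_rhs.append(np.array([lo]))
            continue
        if hi is not None:
            A_ub_rows.append(row)
            b_ub.append(float(hi))
        if lo is not None:
            A_ub_rows.append(-row)
            b_ub.append(-float(lo))
    A_eq = np.vstack(eq_rows)
    b_eq = np.concatenate(eq_rhs)
    A_ub = np.vstack(A_ub_rows) if A_ub_rows else None
    b_ub = np.array(b_ub) if A_ub_rows else None
    return A_eq, b_eq, A_ub, b_ub, model.bounds_list()


def fba(
    model: MetabolicModel,
    objective=None,
    *,
    maximize: bool = True,
    extra_constraints=None,
) -> FluxDistribution:
    """Flux balance analysis: optimize a linear flux objective at steady state.

    Raises :class:`~ctxcut._solver.InfeasibleError` if the polytope is empty
    and :class:`~ctxcut._solver.UnboundedError` if the objective diverges.
    """
    c = model.objective_vector(objective)
    A_eq, b_eq, A_ub, b_ub, bounds = _steady_state_system(model, extra_constraints)
    x, obj = solve_lp(
        c, A_eq=A_eq, b_eq=b_eq, A_ub=A_ub, b_ub=b_ub, bounds=bounds, maximize=maximize
    )
    return FluxDistribution(list(model.reaction_ids), x, obj)


def fva(
    model: MetabolicModel,
    reactions=None,
    *,
    extra_constraints=None,
) -> FvaResult:
    """Flux variability analysis: two LPs per reaction over the constrained polytope.

    Directions that the solver reports unbounded are clipped to the default
    bound magnitude so intervals stay finite and comparable.
    """
    if reactions is None:
        reactions = list(model.reaction_ids)
    unknown = [r for r in reactions if r not in set(model.reaction_ids)]
    if unknown:
        raise KeyError(f"unknown reaction ids: {unknown}")
    A_eq, b_eq, A_ub, b_ub, bounds = _steady_state_system(model, extra_constraints)
    n = model.n_reactions
    ranges = {}
    for rid in reactions:
        c = np.zeros(n)
        c[model.index(rid)] = 1.0
        lohi = []
        for maximize in (False, True):
            try:
                _, obj = solve_lp(
                    c, A_eq=A_eq, b_eq=b_eq, A_ub=A_ub, b_ub=b_ub,
                    bounds=bounds, maximize=maximize,
                )
            except UnboundedError:
                obj = DEFAULT_BOUND if maximize else -DEFAULT_BOUND
            lohi.append(float(np.clip(obj, -DEFAULT_BOUND, DEFAULT_BOUND)))
        ranges[rid] = (lohi[0], lohi[1])
    return FvaResult(ranges)


def find_blocked_fva(model: MetabolicModel, tol: float = BLOCKED_TOL) -> set[str]:
    """Reference blocked-reaction detector: FVA interval equal to {0} within tol.

    This is the oracle the heuristic checkers in :mod:`ctxcut.mba_family` are
    compared against.
    """
    if model.n_reactions == 0:
        return set()
    return fva(model).blocked(tol)


# ---------------------------------------------------------------------------
# Structural transformations
# ---------------------------------------------------------------------------

@dataclass
class SplitMapping:
    """Book-keeping for :func:`split_reversible`.

    ``forward``/``reverse`` map original reaction ids to the column ids of the
    irreversible form; irreversible reactions keep their id as ``forward`` and
    have no ``reverse`` entry.  ``merge`` reconstructs original fluxes.
    """

    forward: dict[str, str]
    reverse: dict[str, str]

    def merge(self, split_model: MetabolicModel, values: np.ndarray) -> dict[str, float]:
        idx = {rid: i for i, rid in enumerate(split_model.reaction_ids)}
        out = {}
        for orig, fwd in self.forward.items():
            v = float(values[idx[fwd]])
            if orig in self.reverse:
                v -= float(values[idx[self.reverse[orig]]])
            out[orig] = v
        return out


def split_reversible(model: MetabolicModel) -> tuple[MetabolicModel, SplitMapping]:
    """Replace every reaction able to run backwards by non-negative
    forward/reverse columns with stoichiometry ``+S_i`` / ``-S_i``.

    A reversible reaction with bounds ``(-5, 10)`` becomes two irreversible
    reactions bounded ``(0, 10)`` and ``(0, 5)``; feasible flux sets correspond
    via ``v = v_for - v_rev``.
    """
    rids, cols, lbs, ubs = [], [], [], []
    gpr = {}
    forward, reverse = {}, {}
    for i, rid in enumerate(model.reaction_ids):
        lo, hi = float(model.lb[i]), float(model.ub[i])
        if lo >= 0:
            rids.append(rid)
            cols.append(model.S[:, i])
            lbs.append(lo)
            ubs.append(hi)
            forward[rid] = rid
            if rid in model.gpr:
                gpr[rid] = model.gpr[rid]
            continue
        fwd, rev = f"{rid}__fwd", f"{rid}__rev"
        rids.extend([fwd, rev])
        cols.extend([model.S[:, i], -model.S[:, i]])
        lbs.extend([0.0, max(0.0, -hi)])
        ubs.extend([max(0.0, hi), -lo])
        forward[rid], reverse[rid] = fwd, rev
        if rid in model.gpr:
            gpr[fwd] = model.gpr[rid]
            gpr[rev] = model.gpr[rid]
    S = np.column_stack(cols) if cols else np.zeros((model.n_metabolites, 0))
    split = MetabolicModel(rids, list(model.metabolite_ids), S, np.array(lbs), np.array(ubs), gpr)
    return split, SplitMapping(forward, reverse)


def flip_reaction(model: MetabolicModel, reaction_id: str) -> MetabolicModel:
    """Reverse the sense of one reaction: negate its column, bounds become
    ``(-v_max, -v_min)``.  Applying it twice restores the model."""
    i = model.index(reaction_id)
    out = model.copy()
    out.S[:, i] = -out.S[:, i]
    out.lb[i], out.ub[i] = -model.ub[i], -model.lb[i]
    return out


def extract_submodel(model: MetabolicModel, keep) -> MetabolicModel:
    """Submodel with only the ``keep`` reactions; metabolites no longer touched
    by any kept reaction are dropped.  ``keep = []`` gives an empty model."""
    keep = list(keep)
    unknown = sorted(set(keep) - set(model.reaction_ids))
    if unknown:
        raise KeyError(f"unknown reaction ids: {unknown}")
    keep_set = set(keep)
    rxn_idx = [i for i, rid in enumerate(model.reaction_ids) if rid in keep_set]
    sub_S = model.S[:, rxn_idx] if rxn_idx else np.zeros((model.n_metabolites, 0))
    if rxn_idx:
        met_mask = np.any(sub_S != 0, axis=1)
    else:
        met_mask = np.zeros(model.n_metabolites, dtype=bool)
    met_idx = np.where(met_mask)[0]
    reaction_ids = [model.reaction_ids[i] for i in rxn_idx]
    metabolite_ids = [model.metabolite_ids[j] for j in met_idx]
    gpr = {rid: model.gpr[rid] for rid in reaction_ids if rid in model.gpr}
    objective = None
    if model.objective is not None and rxn_idx:
        objective = model.objective[rxn_idx]
        if not np.any(objective):
            objective = None
    return MetabolicModel(
        reaction_ids,
        metabolite_ids,
        sub_S[met_idx, :],
        model.lb[rxn_idx],
        model.ub[rxn_idx],
        gpr,
        objective,
    )
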