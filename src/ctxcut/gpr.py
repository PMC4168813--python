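"""Gene-protein-reaction (GPR) rules and evidence mapping.

A GPR rule is a boolean expression over gene identifiers in which AND encodes
an enzyme complex (limited by its scarcest subunit) and OR encodes isoenzymes
(alternative routes).  Mapping quantitative gene evidence to a reaction level
therefore uses AND = min, OR = max — the standard convention.

Penalty mapping is order-reversed: a complex is as *penalized* as its most
penalized subunit (AND = max) while isoenzymes let the least penalized carry
the reaction (OR = min).  This duality makes, for single-gene rules,
``penalty = I_max - expression`` hold exactly.

Genes absent from a data set are the norm with partial omics coverage; by
default an unknown gene makes its subexpression drop out (neutral element),
and a strict mode raises instead.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GprParseError",
    "GprEvaluationError",
    "GprRule",
    "EvidenceProfile",
    "parse_gpr",
    "map_expression",
    "gimme_penalty",
    "gim3e_penalty",
    "discretize",
    "read_evidence_tsv",
]

logger = logging.getLogger(__name__)

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


class GprParseError(ValueError):
    """Malformed GPR rule text; message carries the offending position."""


class GprEvaluationError(KeyError):
    """A gene in the rule is missing from the data (strict mode only)."""


# Expression tree nodes: ("gene", name) | ("and", [children]) | ("or", [children])


@dataclass(frozen=True)
class GprRule:
    """Parsed boolean gene rule."""

    text: str
    tree: tuple

    def genes(self) -> set[str]:
        out: set[str] = set()

        def walk(node):
            if node[0] == "gene":
                out.add(node[1])
            else:
                for child in node[1]:
                    walk(child)

        walk(self.tree)
        return out

    def evaluate(self, values, *, and_op=min, or_op=max, missing: str = "ignore"):
        """Fold the tree with the given operators.

        ``missing='ignore'`` treats unknown genes as neutral (the subexpression
        drops out); an all-unknown rule evaluates to ``None`` ("no data").
        ``missing='strict'`` raises :class:`GprEvaluationError`.
        """

        def walk(node):
            if node[0] == "gene":
                gene = node[1]
                if gene in values:
                    return values[gene]
                if missing == "strict":
                    raise GprEvaluationError(f"gene {gene!r} absent from the data")
                logger.debug("gene %r absent from data; ignored in rule %r", gene, self.text)
                return None
            op = and_op if node[0] == "and" else or_op
            vals = [walk(child) for child in node[1]]
            vals = [v for v in vals if v is not None]
            return op(vals) if vals else None

        return walk(self.tree)


def _tokenize(text: str):
    tokens = []
    for m in _TOKEN_RE.finditer(text):
        tok = m.group(0)
        tokens.append((tok, m.start()))
    return tokens


def parse_gpr(rule_text: str) -> GprRule | None:
    """Parse a rule such as ``"g1 and (g2 or g3)"`` into a tree.

    AND binds tighter than OR; both are case-insensitive.  Returns ``None``
    for the empty string (absent rule).
    """
    if rule_text is None or not rule_text.strip():
        return None
    tokens = _tokenize(rule_text)
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else (None, len(rule_text))

    def error(msg, at):
        raise GprParseError(f"{msg} at position {at} in {rule_text!r}")

    def parse_or():
        nonlocal pos
        parts = [parse_and()]
        while True:
            tok, at = peek()
            if tok is not None and tok.lower() == "or":
                pos += 1
                parts.append(parse_and())
            else:
                break
        return parts[0] if len(parts) == 1 else ("or", parts)

    def parse_and():
        nonlocal pos
        parts = [parse_atom()]
        while True:
            tok, at = peek()
            if tok is not None and tok.lower() == "and":
                pos += 1
                parts.append(parse_atom())
            else:
                break
        return parts[0] if len(parts) == 1 else ("and", parts)

    def parse_atom():
        nonlocal pos
        tok, at = peek()
        if tok is None:
            error("unexpected end of rule", at)
        if tok == "(":
            pos += 1
            node = parse_or()
            tok2, at2 = peek()
            if tok2 != ")":
                error("unbalanced parenthesis", at2)
            pos += 1
            return node
        if tok == ")":
            error("unbalanced parenthesis", at)
        if tok.lower() in {"and", "or"}:
            error(f"dangling operator {tok!r}", at)
        pos += 1
        return ("gene", tok)

    tree = parse_or()
    tok, at = peek()
    if tok is not None:
        if tok == ")":
            raise GprParseError(f"unbalanced parenthesis at position {at} in {rule_text!r}")
        raise GprParseError(f"unexpected token {tok!r} at position {at} in {rule_text!r}")
    return GprRule(rule_text, tree)


def _rules(model) -> dict[str, GprRule]:
    out = {}
    for rid, text in model.gpr.items():
        rule = parse_gpr(text)
        if rule is not None:
            out[rid] = rule
    return out


def map_expression(model, gene_values: dict[str, float], *, missing: str = "ignore") -> dict[str, float]:
    """Map gene intensities to reaction-level data via GPR rules.

    AND -> min (complex limited by scarcest subunit), OR -> max (isoenzymes).
    Reactions without a rule, or whose genes are entirely absent from the
    data, are omitted from the result — "no data", never a fabricated value.
    """
    if not gene_values:
        raise ValueError("gene_values is empty")
    out = {}
    for rid, rule in _rules(model).items():
        value = rule.evaluate(gene_values, and_op=min, or_op=max, missing=missing)
        if value is not None:
            out[rid] = float(value)
    return out


def gimme_penalty(reaction_data: dict[str, float], threshold: float, reaction_ids=None) -> dict[str, float]:
    """GIMME penalties: ``p_i = c - d_i`` where expression falls below the
    cut-off ``c``, zero otherwise.  Reactions without data get zero."""
    ids = list(reaction_ids) if reaction_ids is not None else list(reaction_data)
    return {
        rid: max(0.0, float(threshold) - float(reaction_data[rid])) if rid in reaction_data else 0.0
        for rid in ids
    }


def gim3e_penalty(model, gene_values: dict[str, float], *, i_max: float | None = None,
                  missing: str = "ignore") -> dict[str, float]:
    """GIM3E penalties: per-gene distance to the sample maximum, mapped to
    reactions with the dual convention (OR -> min, AND -> max).

    Every reaction with a (resolvable) rule receives a penalty — in contrast
    with GIMME, where only sub-threshold reactions do.
    """
    if not gene_values:
        raise ValueError("gene_values is empty")
    if i_max is None:
        i_max = max(gene_values.values())
    gene_penalty = {g: float(i_max) - float(v) for g, v in gene_values.items()}
    out = {}
    for rid in model.reaction_ids:
        rule_text = model.gpr.get(rid)
        if not rule_text:
            out[rid] = 0.0
            continue
        rule = parse_gpr(rule_text)
        value = rule.evaluate(gene_penalty, and_op=max, or_op=min, missing=missing)
        out[rid] = 0.0 if value is None else float(value)
    return out


def discretize(
    reaction_data: dict[str, float],
    low_q: float | None = None,
    high_q: float | None = None,
    *,
    c_low: float | None = None,
    c_high: float | None = None,
) -> tuple[set[str], set[str]]:
    """Classify reactions into highly (R_H) and lowly (R_L) expressed sets.

    Quantile mode (``low_q``/``high_q``): thresholds are empirical quantiles
    with linear interpolation; ``R_H = {d >= q_high}``, ``R_L = {d <= q_low}``.
    Absolute mode (``c_low``/``c_high``) uses the given data-unit cut-offs.
    On ties that would land a reaction in both sets, high wins, keeping the
    sets disjoint.
    """
    if not reaction_data:
        raise ValueError("reaction_data is empty")
    values = np.array(list(reaction_data.values()), dtype=float)
    if c_low is not None or c_high is not None:
        if c_low is None or c_high is None:
            raise ValueError("absolute mode needs both c_low and c_high")
        lo_thr, hi_thr = float(c_low), float(c_high)
    else:
        if low_q is None or high_q is None:
            raise ValueError("quantile mode needs both low_q and high_q")
        if not (0 <= low_q < high_q <= 1):
            raise ValueError("require 0 <= low_q < high_q <= 1")
        lo_thr = float(np.quantile(values, low_q))
        hi_thr = float(np.quantile(values, high_q))
        if math.isclose(lo_thr, hi_thr):
            raise ValueError(
                "low and high quantile thresholds coincide (near-constant data); "
                "use absolute thresholds c_low/c_high instead"
            )
    r_h = {rid for rid, d in reaction_data.items() if d >= hi_thr}
    r_l = {rid for rid, d in reaction_data.items() if d <= lo_thr} - r_h
    return r_h, r_l


@dataclass
class EvidenceProfile:
    """Gene-level evidence and its reaction-level derivatives.

    ``I_max`` is the sample maximum intensity; ``reaction_data`` is computed
    lazily from the model's GPR rules.
    """

    gene_values: dict[str, float]
    threshold: float | None = None
    weights: dict[str, float] = field(default_factory=dict)

    @property
    def i_max(self) -> float:
        if not self.gene_values:
            raise ValueError("empty evidence profile has no I_max")
        return max(self.gene_values.values())

    def reaction_data(self, model, *, missing: str = "ignore") -> dict[str, float]:
        return map_expression(model, self.gene_values, missing=missing)


def read_evidence_tsv(path) -> dict[str, float]:
    """Read a two-column TSV (identifier, value); a header line is optional."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"evidence TSV {path} needs two columns")
    first_val = df.iloc[0, 1]
    try:
        float(first_val)
        start = 0
    except (TypeError, ValueError):
        start = 1  # header row
    body = df.iloc[start:]
    return {str(k): float(v) for k, v in zip(body.iloc[:, 0], body.iloc[:, 1])}
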