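"""Flux-balance constraints: linear objectives and per-reaction bounds.

The language encodes constraint-based (FBA-style) models as a linear
objective over reaction fluxes plus inequality constraints::

    OBJF: maximize R16 + R03
    constraint c0: R16 >= 0
    constraint c1: R16 <= 1000

No LP solver lives here: the deliverables are the record itself, the
folded per-reaction bounds table, and FBC-v1 SBML serialization.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .diagnostics import DiagnosticSink, LanguageError, SourceLocation
from .syntax import (Binary, ConstraintStmt, Expr, Num, ObjectiveStmt, Sym,
                     Unary, format_number)

INF = float("inf")


@dataclass(frozen=True)
class Objective:
    id: str
    sense: str                                # "maximize" | "minimize"
    terms: Tuple[Tuple[str, float], ...]      # (reaction id, coefficient)


@dataclass(frozen=True)
class FluxConstraint:
    id: str
    reaction: str
    comparator: str                           # "<=" | ">=" | "="
    bound: float


@dataclass
class FbcRecord:
    objectives: List[Objective] = field(default_factory=list)
    constraints: List[FluxConstraint] = field(default_factory=list)

    def is_empty(self) -> bool:
        return not self.objectives and not self.constraints

    @property
    def active_objective(self) -> Optional[Objective]:
        return self.objectives[0] if self.objectives else None


def linear_terms(expr: Expr) -> List[Tuple[str, float]]:
    """Flatten ``c1*R1 + c2*R2 - R3`` into (reaction, coefficient) pairs.

    Raises :class:`LanguageError` for anything non-linear.
    """
    terms: List[Tuple[str, float]] = []

    def walk(e: Expr, sign: float) -> None:
        if isinstance(e, Binary) and e.op == "+":
            walk(e.left, sign)
            walk(e.right, sign)
            return
        if isinstance(e, Binary) and e.op == "-":
            walk(e.left, sign)
            walk(e.right, -sign)
            return
        if isinstance(e, Unary) and e.op == "-":
            walk(e.child, -sign)
            return
        if isinstance(e, Sym):
            terms.append((e.name, sign))
            return
        if isinstance(e, Binary) and e.op == "*":
            coeff, sym = e.left, e.right
            if isinstance(coeff, Sym) and isinstance(sym, (Num, Unary)):
                coeff, sym = sym, coeff
            cv = _number(coeff)
            if cv is not None and isinstance(sym, Sym):
                terms.append((sym.name, sign * cv))
                return
        raise LanguageError(
            "objective must be a linear combination of reaction fluxes")

    walk(expr, 1.0)
    return terms


def _number(e: Expr) -> Optional[float]:
    if isinstance(e, Num):
        return e.value
    if isinstance(e, Unary) and e.op == "-":
        v = _number(e.child)
        return None if v is None else -v
    return None


def build_fbc(reaction_ids: Sequence[str],
              objectives: Sequence[ObjectiveStmt],
              constraints: Sequence[ConstraintStmt],
              sink: DiagnosticSink) -> FbcRecord:
    """Collect objectives and constraints in source order.

    Objective terms and constraints must reference declared reactions;
    duplicate constraint ids are an error.  Reactions left without a
    finite lower or upper bound draw a warning (a complete
    constraint-based model bounds every flux, possibly at +/-inf).
    """
    rec = FbcRecord()
    known = set(reaction_ids)
    for stmt in objectives:
        try:
            terms = linear_terms(stmt.formula)
        except LanguageError as exc:
            sink.error(exc.message, stmt.loc)
            continue
        bad = [r for r, _ in terms if r not in known]
        if bad:
            sink.error(f"objective '{stmt.name}' references "
                       f"non-reaction symbol '{bad[0]}'", stmt.loc)
            continue
        rec.objectives.append(Objective(stmt.name, stmt.sense, tuple(terms)))
    seen_ids = set()
    for stmt in constraints:
        if stmt.name in seen_ids:
            sink.error(f"duplicate constraint id '{stmt.name}'", stmt.loc)
            continue
        seen_ids.add(stmt.name)
        if stmt.reaction not in known:
            sink.error(f"constraint '{stmt.name}' references non-reaction "
                       f"symbol '{stmt.reaction}'", stmt.loc)
            continue
        rec.constraints.append(FluxConstraint(stmt.name, stmt.reaction,
                                              stmt.comparator, stmt.bound))
    if not rec.is_empty():
        table = {}
        try:
            table = bounds_table(rec)
        except LanguageError:
            pass  # infeasibility surfaces when bounds_table is called directly
        unbounded = [r for r in reaction_ids
                     if r not in table
                     or table[r][0] == -INF or table[r][1] == INF]
        if unbounded:
            sink.warn("reactions without both flux bounds: "
                      + ", ".join(unbounded))
    return rec


def bounds_table(rec: FbcRecord) -> Dict[str, Tuple[float, float]]:
    """Fold constraints into per-reaction (lower, upper) bounds.

    ``>=`` raises the lower bound, ``<=`` lowers the upper bound, ``=``
    pins both.  A crossed pair (lower > upper) is an infeasibility
    error naming the reaction.
    """
    table: Dict[str, List[float]] = {}
    for c in rec.constraints:
        lo, hi = table.setdefault(c.reaction, [-INF, INF])
        if c.comparator == ">=":
            table[c.reaction][0] = max(lo, c.bound)
        elif c.comparator == "<=":
            table[c.reaction][1] = min(hi, c.bound)
        else:  # "="
            table[c.reaction][0] = max(lo, c.bound)
            table[c.reaction][1] = min(hi, c.bound)
    for reaction, (lo, hi) in table.items():
        if lo > hi:
            raise LanguageError(
                f"infeasible flux bounds for '{reaction}': "
                f"lower {format_number(lo)} > upper {format_number(hi)}")
    return {r: (lo, hi) for r, (lo, hi) in table.items()}


def unparse_fbc(rec: FbcRecord) -> List[str]:
    """Canonical objective/constraint statements, one per line."""
    out: List[str] = []
    for obj in rec.objectives:
        parts = []
        for reaction, coeff in obj.terms:
            parts.append(reaction if coeff == 1.0
                         else f"{format_number(coeff)}*{reaction}")
        out.append(f"{obj.id}: {obj.sense} " + " + ".join(parts))
    for c in rec.constraints:
        out.append(f"constraint {c.id}: {c.reaction} {c.comparator} "
                   f"{format_number(c.bound)}")
    return out
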