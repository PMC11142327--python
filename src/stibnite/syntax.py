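"""Abstract syntax for the Antimony dialect.

Expressions are immutable operator trees over numbers, symbols, the
integrator clock ``time`` and function calls (including ``rateOf`` and
distribution draws).  Statements carry a :class:`SourceLocation` and one
variant-specific payload.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

from .diagnostics import SourceLocation

# --------------------------------------------------------------------------
# Expressions
# --------------------------------------------------------------------------


class Expr:
    """Base class for expression nodes."""

    __slots__ = ()


@dataclass(frozen=True)
class Num(Expr):
    value: float


@dataclass(frozen=True)
class Sym(Expr):
    name: str


@dataclass(frozen=True)
class TimeSym(Expr):
    """The simulation clock (``time`` keyword)."""


@dataclass(frozen=True)
class Unary(Expr):
    op: str  # only "-"
    child: Expr


@dataclass(frozen=True)
class Binary(Expr):
    op: str  # + - * / ^ and comparators > < >= <= == !=
    left: Expr
    right: Expr


@dataclass(frozen=True)
class Call(Expr):
    callee: str
    args: Tuple[Expr, ...]


_COMPARATORS = {">", "<", ">=", "<=", "==", "!="}

# precedence for unparsing; higher binds tighter
_PREC = {
    "==": 1, "!=": 1, ">": 1, "<": 1, ">=": 1, "<=": 1,
    "+": 2, "-": 2,
    "*": 3, "/": 3,
    "neg": 4,
    "^": 5,
}


def format_number(value: float) -> str:
    """Canonical decimal rendering: integers without a trailing ``.0``."""
    if math.isinf(value):
        return "inf" if value > 0 else "-inf"
    if value == int(value) and abs(value) < 1e16:
        return str(int(value))
    return repr(value)


def unparse_expr(expr: Expr) -> str:
    """Render an expression with minimal parentheses (canonical ASCII)."""
    return _unparse(expr, 0)


def _unparse(expr: Expr, parent_prec: int) -> str:
    if isinstance(expr, Num):
        return format_number(expr.value)
    if isinstance(expr, Sym):
        return expr.name
    if isinstance(expr, TimeSym):
        return "time"
    if isinstance(expr, Call):
        args = ", ".join(_unparse(a, 0) for a in expr.args)
        return f"{expr.callee}({args})"
    if isinstance(expr, Unary):
        prec = _PREC["neg"]
        inner = _unparse(expr.child, prec)
        text = f"-{inner}"
        return f"({text})" if parent_prec > prec else text
    if isinstance(expr, Binary):
        prec = _PREC[expr.op]
        # left-assoc ops: right child needs a bump; ^ is right-assoc
        if expr.op == "^":
            left = _unparse(expr.left, prec + 1)
            right = _unparse(expr.right, prec)
        else:
            left = _unparse(expr.left, prec)
            right = _unparse(expr.right, prec + 1)
        text = f"{left} {expr.op} {right}"
        return f"({text})" if parent_prec > prec else text
    raise TypeError(f"not an expression node: {expr!r}")


def expr_symbols(expr: Expr) -> List[str]:
    """All symbol names referenced, in first-appearance order."""
    out: List[str] = []
    seen = set()

    def walk(e: Expr) -> None:
        if isinstance(e, Sym):
            if e.name not in seen:
                seen.add(e.name)
                out.append(e.name)
        elif isinstance(e, Unary):
            walk(e.child)
        elif isinstance(e, Binary):
            walk(e.left)
            walk(e.right)
        elif isinstance(e, Call):
            for a in e.args:
                walk(a)

    walk(expr)
    return out


def expr_calls(expr: Expr) -> List[Call]:
    """All call nodes, outermost first."""
    out: List[Call] = []

    def walk(e: Expr) -> None:
        if isinstance(e, Call):
            out.append(e)
            for a in e.args:
                walk(a)
        elif isinstance(e, Unary):
            walk(e.child)
        elif isinstance(e, Binary):
            walk(e.left)
            walk(e.right)

    walk(expr)
    return out


# --------------------------------------------------------------------------
# Statements
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class AstParticipant:
    """One reactant or product: ``[$][stoich] species``."""

    species: str
    stoichiometry: Union[float, str] = 1.0  # number or symbol name
    boundary: bool = False


class Stmt:
    __slots__ = ()


@dataclass(frozen=True)
class ReactionStmt(Stmt):
    loc: SourceLocation
    name: Optional[str]
    reactants: Tuple[AstParticipant, ...]
    products: Tuple[AstParticipant, ...]
    rate_law: Optional[Expr]


@dataclass(frozen=True)
class InitAssignStmt(Stmt):
    loc: SourceLocation
    target: str
    boundary_mark: bool
    formula: Expr


@dataclass(frozen=True)
class ContAssignStmt(Stmt):
    loc: SourceLocation
    target: str
    boundary_mark: bool
    formula: Expr


@dataclass(frozen=True)
class RateRuleStmt(Stmt):
    loc: SourceLocation
    target: str
    boundary_mark: bool
    formula: Expr


@dataclass(frozen=True)
class AlgRuleStmt(Stmt):
    loc: SourceLocation
    name: Optional[str]
    formula: Expr


@dataclass(frozen=True)
class EventStmt(Stmt):
    loc: SourceLocation
    trigger: Expr
    assignments: Tuple[Tuple[str, Expr], ...]


@dataclass(frozen=True)
class MetadataStmt(Stmt):
    loc: SourceLocation
    keyword: str            # e.g. "notes", "creator1.givenName"
    value: str


@dataclass(frozen=True)
class ObjectiveStmt(Stmt):
    loc: SourceLocation
    name: str
    sense: str              # "maximize" | "minimize"
    formula: Expr


@dataclass(frozen=True)
class ConstraintStmt(Stmt):
    loc: SourceLocation
    name: str
    reaction: str
    comparator: str         # "<=" | ">=" | "="
    bound: float


@dataclass(frozen=True)
class UncertaintyStmt(Stmt):
    loc: SourceLocation
    target: str
    attribute: str
    # exactly one of the following three is set
    scalar: Optional[Expr] = None
    pair: Optional[Tuple[Expr, Expr]] = None
    uri: Optional[str] = None


@dataclass(frozen=True)
class ModelBeginStmt(Stmt):
    loc: SourceLocation
    name: str


@dataclass(frozen=True)
class ModelEndStmt(Stmt):
    loc: SourceLocation


def is_comparator(op: str) -> bool:
    return op in _COMPARATORS
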