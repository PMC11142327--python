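"""Semantic model: symbol resolution, classification and validation.

The builder turns a parsed statement sequence into a :class:`Model`:

* identifiers appearing in a reaction participant list are *species*;
* identifiers seen only in formulas/assignments are *parameters*;
* ``$`` marks a boundary species (its amount is not changed by the
  reactions it takes part in);
* a species that participates in reactions while being the target of a
  rate rule or a continuous assignment must carry ``$`` — otherwise the
  reaction ODE and the rule would both claim its derivative;
* symbolic stoichiometries (``n S1``) declare parameters.

All species live in a single implicit compartment ``default_compartment``
of size 1, so concentrations and amounts coincide numerically.
Uninitialized symbols default to 0 with a warning.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Sequence, Set, Tuple, Union

from . import distributions, fbc as fbc_mod, metadata as meta_mod
from .diagnostics import Diagnostic, DiagnosticSink, LanguageError, Severity
from .syntax import (AlgRuleStmt, AstParticipant, Call, ConstraintStmt,
                     ContAssignStmt, EventStmt, Expr, InitAssignStmt,
                     MetadataStmt, ModelBeginStmt, ModelEndStmt, Num,
                     ObjectiveStmt, RateRuleStmt, ReactionStmt, Stmt, Sym,
                     UncertaintyStmt, expr_calls, expr_symbols, unparse_expr,
                     format_number)

DEFAULT_COMPARTMENT = "default_compartment"

#: function names with numeric semantics (beyond distributions and rateOf)
MATH_FUNCTIONS = frozenset({
    "abs", "ceil", "ceiling", "cos", "cosh", "exp", "floor", "ln", "log",
    "log10", "pow", "root", "sin", "sinh", "sqrt", "tan", "tanh",
    "arcsin", "arccos", "arctan", "asin", "acos", "atan", "piecewise",
})

_KEYWORDS = frozenset({"model", "end", "if", "constraint", "maximize",
                       "minimize", "is", "time"})


@dataclass
class Participant:
    species: str
    stoichiometry: Union[float, str] = 1.0


@dataclass
class Species:
    id: str
    boundary: bool = False
    initial: Optional[Expr] = None
    compartment: str = DEFAULT_COMPARTMENT


@dataclass
class Parameter:
    id: str
    initial: Optional[Expr] = None
    constant: bool = True


@dataclass
class Reaction:
    id: str
    reactants: List[Participant] = field(default_factory=list)
    products: List[Participant] = field(default_factory=list)
    kinetic_law: Optional[Expr] = None
    reversible: bool = True


@dataclass
class Rule:
    kind: str                      # "continuous" | "rate" | "algebraic"
    target: Optional[str]          # None for algebraic
    formula: Expr = Num(0.0)
    name: Optional[str] = None     # algebraic rules may carry a label


@dataclass
class Event:
    id: str
    trigger: Expr
    assignments: List[Tuple[str, Expr]] = field(default_factory=list)


@dataclass
class Model:
    name: Optional[str] = None
    species: Dict[str, Species] = field(default_factory=dict)
    parameters: Dict[str, Parameter] = field(default_factory=dict)
    reactions: Dict[str, Reaction] = field(default_factory=dict)
    rules: List[Rule] = field(default_factory=list)
    events: List[Event] = field(default_factory=list)
    metadata: meta_mod.MetadataRecord = field(
        default_factory=meta_mod.MetadataRecord)
    uncertainty: Dict[str, distributions.UncertaintyRecord] = field(
        default_factory=dict)
    fbc: fbc_mod.FbcRecord = field(default_factory=fbc_mod.FbcRecord)
    # dict used as an ordered set: insertion order is declaration order
    stoich_symbols: Dict[str, None] = field(default_factory=dict)
    diagnostics: DiagnosticSink = field(default_factory=DiagnosticSink)

    # -- lookups -----------------------------------------------------------
    def has_symbol(self, name: str) -> bool:
        return (name in self.species or name in self.parameters
                or name in self.reactions)

    def continuous_targets(self) -> Set[str]:
        return {r.target for r in self.rules
                if r.kind == "continuous" and r.target}

    def rate_targets(self) -> Set[str]:
        return {r.target for r in self.rules if r.kind == "rate" and r.target}

    def rule_for(self, target: str, kind: str) -> Optional[Rule]:
        for r in self.rules:
            if r.kind == kind and r.target == target:
                return r
        return None

    def algebraic_rules(self) -> List[Rule]:
        return [r for r in self.rules if r.kind == "algebraic"]

    def initial_of(self, name: str) -> Optional[Expr]:
        if name in self.species:
            return self.species[name].initial
        if name in self.parameters:
            return self.parameters[name].initial
        return None

    def all_expressions(self) -> Iterator[Tuple[str, Expr]]:
        """(context, expression) pairs over the whole model.

        Contexts: ``kinetic-law``, ``continuous``, ``rate``,
        ``algebraic``, ``initial``, ``event-trigger``,
        ``event-assignment``, ``uncertainty``.
        """
        for rxn in self.reactions.values():
            if rxn.kinetic_law is not None:
                yield "kinetic-law", rxn.kinetic_law
        for rule in self.rules:
            yield rule.kind, rule.formula
        for sp in self.species.values():
            if sp.initial is not None:
                yield "initial", sp.initial
        for par in self.parameters.values():
            if par.initial is not None:
                yield "initial", par.initial
        for ev in self.events:
            yield "event-trigger", ev.trigger
            for _, expr in ev.assignments:
                yield "event-assignment", expr
        for rec in self.uncertainty.values():
            for e in rec.scalars.values():
                yield "uncertainty", e
            for lo, hi in rec.intervals.values():
                yield "uncertainty", lo
                yield "uncertainty", hi
            if isinstance(rec.distribution, Expr):
                yield "uncertainty", rec.distribution
            if isinstance(rec.external_parameter, Expr):
                yield "uncertainty", rec.external_parameter
            elif isinstance(rec.external_parameter, tuple):
                yield "uncertainty", rec.external_parameter[0]
                yield "uncertainty", rec.external_parameter[1]


# --------------------------------------------------------------------------
# Builder
# --------------------------------------------------------------------------


def build_model(statements: Sequence[Stmt],
                sink: Optional[DiagnosticSink] = None) -> Model:
    """Resolve a statement sequence into a validated Model.

    Errors and warnings accumulate in ``model.diagnostics``; builders
    never raise for model-level problems, so tools can report all
    diagnostics at once.
    """
    sink = sink or DiagnosticSink()
    m = Model(diagnostics=sink)
    in_block = False
    block_seen = False
    meta_stmts: List[Tuple[MetadataStmt, bool]] = []
    obj_stmts: List[ObjectiveStmt] = []
    con_stmts: List[ConstraintStmt] = []
    unc_stmts: List[UncertaintyStmt] = []
    auto_rxn = 0

    # pass A: reactions declare species (participant order) and reaction ids
    for stmt in statements:
        if not isinstance(stmt, ReactionStmt):
            continue
        rid = stmt.name
        if rid is None:
            rid = f"_J{auto_rxn}"
            auto_rxn += 1
        if rid in m.reactions:
            sink.error(f"duplicate reaction id '{rid}'", stmt.loc)
            continue
        rxn = Reaction(rid)
        for side, out in ((stmt.reactants, rxn.reactants),
                          (stmt.products, rxn.products)):
            for part in side:
                sp = m.species.get(part.species)
                if sp is None:
                    sp = Species(part.species)
                    m.species[part.species] = sp
                if part.boundary:
                    sp.boundary = True
                out.append(Participant(part.species, part.stoichiometry))
                if isinstance(part.stoichiometry, str):
                    m.stoich_symbols.setdefault(part.stoichiometry, None)
        rxn.kinetic_law = stmt.rate_law
        m.reactions[rid] = rxn

    for name in m.stoich_symbols:
        if name in m.species:
            m.diagnostics.error(
                f"stoichiometry symbol '{name}' is also a species")
        elif name not in m.parameters:
            m.parameters[name] = Parameter(name)

    def ensure_param(name: str) -> Optional[Parameter]:
        if name in m.species:
            return None
        if name in m.reactions:
            return None
        return m.parameters.setdefault(name, Parameter(name))

    # pass B: remaining statements in source order
    for stmt in statements:
        if isinstance(stmt, ReactionStmt):
            continue
        if isinstance(stmt, ModelBeginStmt):
            if block_seen:
                sink.error("model blocks may not nest or repeat", stmt.loc)
                continue
            in_block = True
            block_seen = True
            m.name = stmt.name
        elif isinstance(stmt, ModelEndStmt):
            if not in_block:
                sink.error("'end' without a matching 'model name()'",
                           stmt.loc)
            in_block = False
        elif isinstance(stmt, MetadataStmt):
            meta_stmts.append((stmt, in_block))
        elif isinstance(stmt, InitAssignStmt):
            _apply_initial(m, stmt, sink)
        elif isinstance(stmt, ContAssignStmt):
            _apply_rule(m, stmt, "continuous", sink)
        elif isinstance(stmt, RateRuleStmt):
            _apply_rule(m, stmt, "rate", sink)
        elif isinstance(stmt, AlgRuleStmt):
            m.rules.append(Rule("algebraic", None, stmt.formula, stmt.name))
        elif isinstance(stmt, EventStmt):
            ev = Event(f"_E{len(m.events)}", stmt.trigger,
                       list(stmt.assignments))
            for target, _ in ev.assignments:
                if target in m.reactions:
                    sink.error(f"event assigns to reaction '{target}'",
                               stmt.loc)
                    continue
                p = ensure_param(target)
                if p is not None:
                    p.constant = False
            m.events.append(ev)
        elif isinstance(stmt, ObjectiveStmt):
            obj_stmts.append(stmt)
        elif isinstance(stmt, ConstraintStmt):
            con_stmts.append(stmt)
        elif isinstance(stmt, UncertaintyStmt):
            unc_stmts.append(stmt)
        else:  # pragma: no cover - parser produces no other variants
            sink.error(f"unhandled statement {type(stmt).__name__}", stmt.loc)

    # pass C: auto-declare expression symbols, check callees
    for _, expr in list(m.all_expressions()):
        _resolve_expr(m, expr, sink)
    for stmt in obj_stmts + con_stmts:
        pass  # fbc references are checked by build_fbc against reactions

    # pass D: structural checks
    _check_rules(m, sink)
    _check_cycles(m, sink)
    _warn_uninitialized(m, sink)

    # pass E: metadata / uncertainty / fbc
    m.metadata = meta_mod.build_metadata(meta_stmts, sink)
    _attach_uncertainty(m, unc_stmts, sink)
    m.fbc = fbc_mod.build_fbc(list(m.reactions), obj_stmts, con_stmts, sink)
    for _, expr in list(m.all_expressions()):
        _resolve_expr(m, expr, sink, declare_only=True)
    return m


def _apply_initial(m: Model, stmt: InitAssignStmt,
                   sink: DiagnosticSink) -> None:
    target = stmt.target
    if target in m.reactions:
        sink.error(f"cannot assign a value to reaction '{target}'", stmt.loc)
        return
    if target in m.species:
        sp = m.species[target]
        if stmt.boundary_mark:
            sp.boundary = True
        if sp.initial is not None:
            sink.warn(f"'{target}' initialized more than once; "
                      "last statement wins", stmt.loc)
        sp.initial = stmt.formula
        return
    par = m.parameters.setdefault(target, Parameter(target))
    if par.initial is not None:
        sink.warn(f"'{target}' initialized more than once; "
                  "last statement wins", stmt.loc)
    par.initial = stmt.formula


def _apply_rule(m: Model, stmt, kind: str, sink: DiagnosticSink) -> None:
    target = stmt.target
    if target in m.reactions:
        sink.error(f"{kind} rule targets reaction '{target}'", stmt.loc)
        return
    if target in m.species:
        if stmt.boundary_mark:
            m.species[target].boundary = True
    else:
        par = m.parameters.setdefault(target, Parameter(target))
        par.constant = False
    if m.rule_for(target, kind) is not None:
        sink.error(f"multiple {kind} rules for '{target}'", stmt.loc)
        return
    m.rules.append(Rule(kind, target, stmt.formula))


def _resolve_expr(m: Model, expr: Expr, sink: DiagnosticSink,
                  declare_only: bool = False) -> None:
    for name in expr_symbols(expr):
        if not m.has_symbol(name):
            m.parameters[name] = Parameter(name)
    if declare_only:
        return
    for call in expr_calls(expr):
        if call.callee == "rateOf":
            if len(call.args) != 1 or not isinstance(call.args[0], Sym):
                sink.error("rateOf takes exactly one symbol argument")
            continue
        if call.callee in distributions.DISTRIBUTION_NAMES:
            sink.extend(distributions.validate_distribution(call))
            continue
        if call.callee not in MATH_FUNCTIONS:
            sink.error(f"unknown function '{call.callee}'")


def _check_rules(m: Model, sink: DiagnosticSink) -> None:
    cont = m.continuous_targets()
    rate = m.rate_targets()
    for target in cont & rate:
        sink.error(f"'{target}' has both an assignment rule (':=') and a "
                   "rate rule (\"'\"); they are mutually exclusive")
    in_reactions = {p.species for rxn in m.reactions.values()
                    for p in rxn.reactants + rxn.products}
    for target in sorted((cont | rate) & in_reactions):
        if not m.species[target].boundary:
            which = "assignment" if target in cont else "rate"
            sink.error(f"species '{target}' participates in reactions and "
                       f"has a {which} rule; it must be declared as a "
                       f"boundary species ('${target}')")
    # an algebraic-rule-constrained model cannot also event-assign a
    # fully determined variable; with anonymous algebraic targets we can
    # only check that event targets are not continuous-rule targets
    for ev in m.events:
        for target, _ in ev.assignments:
            if target in cont:
                sink.error(f"event '{ev.id}' assigns to '{target}', which "
                           "is determined by an assignment rule")


def _check_cycles(m: Model, sink: DiagnosticSink) -> None:
    cont = {r.target: r for r in m.rules
            if r.kind == "continuous" and r.target}
    color: Dict[str, int] = {}

    def visit(node: str, trail: List[str]) -> bool:
        color[node] = 1
        for dep in expr_symbols(cont[node].formula):
            if dep not in cont:
                continue
            if color.get(dep) == 1:
                cycle = " -> ".join(trail + [node, dep])
                sink.error(f"cyclic assignment rules: {cycle}")
                return False
            if color.get(dep, 0) == 0 and not visit(dep, trail + [node]):
                return False
        color[node] = 2
        return True

    for node in cont:
        if color.get(node, 0) == 0:
            if not visit(node, []):
                return


def _warn_uninitialized(m: Model, sink: DiagnosticSink) -> None:
    cont = m.continuous_targets()
    for sp in m.species.values():
        if sp.initial is None and sp.id not in cont:
            sink.warn(f"species '{sp.id}' has no initial value; "
                      "defaulting to 0")
    for par in m.parameters.values():
        if par.initial is None and par.id not in cont:
            sink.warn(f"parameter '{par.id}' has no initial value; "
                      "defaulting to 0")


def _attach_uncertainty(m: Model, stmts: Sequence[UncertaintyStmt],
                        sink: DiagnosticSink) -> None:
    for stmt in stmts:
        if stmt.target in _KEYWORDS:
            sink.error(f"'{stmt.target}' is a keyword, not a symbol",
                       stmt.loc)
            continue
        if not m.has_symbol(stmt.target):
            m.parameters[stmt.target] = Parameter(stmt.target)
            sink.warn(f"uncertainty attached to undeclared symbol "
                      f"'{stmt.target}'; declared as a parameter", stmt.loc)
        canon = distributions.canonical_attribute(stmt.attribute)
        if canon is None:
            sink.error(f"unknown uncertainty attribute '{stmt.attribute}'",
                       stmt.loc)
            continue
        rec = m.uncertainty.setdefault(stmt.target,
                                       distributions.UncertaintyRecord())
        if canon in distributions.SCALAR_ATTRIBUTES:
            if stmt.scalar is None:
                sink.error(f"'{canon}' takes a scalar value", stmt.loc)
            else:
                rec.scalars[canon] = stmt.scalar
        elif canon in distributions.INTERVAL_ATTRIBUTES:
            if stmt.pair is None:
                sink.error(f"'{canon}' takes a {{lower, upper}} pair",
                           stmt.loc)
            else:
                rec.intervals[canon] = stmt.pair
        elif canon == "distribution":
            rec.distribution = stmt.uri if stmt.uri is not None else stmt.scalar
            if rec.distribution is None:
                sink.error("'distribution' takes a formula or a URI",
                           stmt.loc)
        else:  # externalParameter
            if stmt.uri is not None:
                rec.external_parameter = stmt.uri
            elif stmt.pair is not None:
                rec.external_parameter = stmt.pair
            elif stmt.scalar is not None:
                rec.external_parameter = stmt.scalar


# --------------------------------------------------------------------------
# Semantic checks exposed separately (diagnostics, never raising)
# --------------------------------------------------------------------------


def check_rateof_usage(model: Model) -> List[Diagnostic]:
    """``rateOf(x)`` is legal only for species and rate-rule targets.

    Applying it to a reaction id or to the target of an assignment rule
    is an error.
    """
    diags: List[Diagnostic] = []
    cont = model.continuous_targets()
    for context, expr in model.all_expressions():
        for call in expr_calls(expr):
            if call.callee != "rateOf" or len(call.args) != 1:
                continue
            arg = call.args[0]
            if not isinstance(arg, Sym):
                diags.append(Diagnostic(
                    Severity.ERROR, "rateOf argument must be a symbol"))
                continue
            if arg.name in model.reactions:
                diags.append(Diagnostic(
                    Severity.ERROR,
                    f"rateOf cannot be applied to reaction '{arg.name}'"))
            elif arg.name in cont:
                diags.append(Diagnostic(
                    Severity.ERROR,
                    f"rateOf cannot be applied to assignment-rule target "
                    f"'{arg.name}'"))
    return diags


_CONTINUOUS_CONTEXTS = {"kinetic-law", "continuous", "rate", "algebraic"}


def check_distribution_contexts(model: Model) -> List[Diagnostic]:
    """Distribution draws may appear only in discrete contexts.

    Initial assignments and event assignments are discrete; kinetic
    laws, assignment rules, rate rules and algebraic rules are
    continuous and may not sample.
    """
    diags: List[Diagnostic] = []
    for context, expr in model.all_expressions():
        if context not in _CONTINUOUS_CONTEXTS:
            continue
        for call in expr_calls(expr):
            if call.callee in distributions.DISTRIBUTION_NAMES:
                diags.append(Diagnostic(
                    Severity.ERROR,
                    f"distribution '{call.callee}' used in a continuous "
                    f"context ({context}); draws are only allowed in "
                    "initial assignments and event assignments"))
    return diags


def run_checks(model: Model) -> DiagnosticSink:
    """Run all post-build semantic checks into the model's sink."""
    model.diagnostics.extend(check_rateof_usage(model))
    model.diagnostics.extend(check_distribution_contexts(model))
    return model.diagnostics


# --------------------------------------------------------------------------
# Canonical unparser
# --------------------------------------------------------------------------


def _participant_text(m: Model, part: Participant) -> str:
    sp = m.species[part.species]
    prefix = ""
    if part.stoichiometry != 1.0:
        s = part.stoichiometry
        prefix = (s if isinstance(s, str) else format_number(s)) + " "
    dollar = "$" if sp.boundary else ""
    return f"{prefix}{dollar}{part.species}"


def unparse(model: Model) -> str:
    """Render a Model as canonical dialect text.

    The output reparses to a semantically identical model, and
    ``unparse(build(parse(text)))`` is a fixed point after one
    application: statements are emitted one per line in a canonical
    order (reactions, assignment/rate/algebraic rules, events, initial
    values, FBC, uncertainty, metadata) with ASCII arrows and minimal
    parentheses.
    """
    lines: List[str] = []
    named = model.name is not None
    if named:
        lines.append(f"model {model.name}()")
    for rxn in model.reactions.values():
        left = " + ".join(_participant_text(model, p) for p in rxn.reactants)
        right = " + ".join(_participant_text(model, p) for p in rxn.products)
        head = f"{rxn.id}: {left} -> {right}"
        if rxn.kinetic_law is not None:
            head += f"; {unparse_expr(rxn.kinetic_law)}"
        lines.append(head)
    for rule in model.rules:
        if rule.kind == "continuous":
            lines.append(f"{rule.target} := {unparse_expr(rule.formula)}")
        elif rule.kind == "rate":
            dollar = "$" if (rule.target in model.species
                             and model.species[rule.target].boundary) else ""
            lines.append(f"{dollar}{rule.target}' = "
                         f"{unparse_expr(rule.formula)}")
        else:
            label = f"{rule.name}: " if rule.name else ""
            lines.append(f"{label}0 = {unparse_expr(rule.formula)}")
    for ev in model.events:
        lines.append(f"if {unparse_expr(ev.trigger)}:")
        for target, expr in ev.assignments:
            lines.append(f"  {target} = {unparse_expr(expr)}")
    for sp in model.species.values():
        if sp.initial is not None:
            lines.append(f"{sp.id} = {unparse_expr(sp.initial)}")
    for par in model.parameters.values():
        if par.initial is not None:
            lines.append(f"{par.id} = {unparse_expr(par.initial)}")
    lines.extend(fbc_mod.unparse_fbc(model.fbc))
    for target, rec in model.uncertainty.items():
        lines.extend(_unparse_uncertainty(target, rec))
    lines.extend(meta_mod.unparse_metadata(model.metadata))
    if named:
        lines.append("end")
    return "\n".join(lines) + ("\n" if lines else "")


def _unparse_uncertainty(target: str,
                         rec: distributions.UncertaintyRecord) -> List[str]:
    out: List[str] = []
    for attr in distributions.SCALAR_ATTRIBUTES:
        if attr in rec.scalars:
            out.append(f"{target}.{attr} = {unparse_expr(rec.scalars[attr])}")
    for attr in distributions.INTERVAL_ATTRIBUTES:
        if attr in rec.intervals:
            lo, hi = rec.intervals[attr]
            out.append(f"{target}.{attr} = "
                       f"{{{unparse_expr(lo)}, {unparse_expr(hi)}}}")
    if rec.distribution is not None:
        if isinstance(rec.distribution, str):
            out.append(f'{target}.distribution is "{rec.distribution}"')
        else:
            out.append(f"{target}.distribution = "
                       f"{unparse_expr(rec.distribution)}")
    ep = rec.external_parameter
    if ep is not None:
        if isinstance(ep, str):
            out.append(f'{target}.externalParameter is "{ep}"')
        elif isinstance(ep, tuple):
            out.append(f"{target}.externalParameter = "
                       f"{{{unparse_expr(ep[0])}, {unparse_expr(ep[1])}}}")
        else:
            out.append(f"{target}.externalParameter = {unparse_expr(ep)}")
    return out


def loads(text: str, sink: Optional[DiagnosticSink] = None) -> Model:
    """Parse, build and fully check a model from dialect text."""
    from .grammar import parse
    model = build_model(parse(text), sink)
    run_checks(model)
    return model
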