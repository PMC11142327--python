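"""Numerical semantics: compile a Model to an ODE + event system.

State variables are the non-boundary, non-assigned species plus all
rate-rule targets; assignment-rule (``:=``) targets are derived
quantities recomputed from the state at every evaluation, including
symbolic stoichiometries, which are therefore re-read on each
right-hand-side call.  For a species S in reactions,

    dS/dt = sum(product stoichiometry * rate) - sum(reactant stoichiometry * rate)

over all reactions S takes part in; boundary (``$``) species receive no
reaction-derived derivative.  ``rateOf(x)`` evaluates to exactly that
right-hand-side component (or the rate-rule formula), and ``time`` is
the integrator clock.

Events fire on a false -> true edge of their trigger, located by
bisection to ``1e-9 * t_end``; assignments are applied atomically using
pre-event values, and a trigger must return to false before it can
fire again.  Triggers that are true at t=0 do not fire until they
first go false.  Distribution draws in initial assignments are sampled
once, before integration, from the seeded stream; draws in event
assignments are sampled at firing time from the same stream.

Models containing algebraic rules are declined: this engine solves
ODEs, not DAEs.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.integrate import solve_ivp

from .diagnostics import LanguageError
from .distributions import DISTRIBUTION_NAMES, RngStream, sample_value
from .model import Model, Participant
from .syntax import (Binary, Call, Expr, Num, Sym, TimeSym, Unary,
                     expr_symbols)

RTOL = 1e-8
ATOL = 1e-12
_EVENT_TOL_FACTOR = 1e-9

_FUNCS: Dict[str, Callable[..., float]] = {
    "sin": math.sin, "cos": math.cos, "tan": math.tan,
    "sinh": math.sinh, "cosh": math.cosh, "tanh": math.tanh,
    "arcsin": math.asin, "arccos": math.acos, "arctan": math.atan,
    "asin": math.asin, "acos": math.acos, "atan": math.atan,
    "exp": math.exp, "ln": math.log, "log": math.log10,
    "log10": math.log10, "sqrt": math.sqrt, "abs": abs,
    "floor": math.floor, "ceil": math.ceil, "ceiling": math.ceil,
    "pow": pow,
}


@dataclass
class Trajectory:
    """Simulation output on a fixed grid, plus the event firing log."""

    time: np.ndarray
    values: Dict[str, np.ndarray]
    event_log: List[Tuple[float, str]] = field(default_factory=list)

    def __getitem__(self, symbol: str) -> np.ndarray:
        return self.values[symbol]


class CompiledSystem:
    """Executable form of a Model: state layout, RHS, events."""

    def __init__(self, model: Model):
        if model.algebraic_rules():
            raise LanguageError(
                "model contains algebraic rules; this engine does not "
                "solve DAE systems")
        self.model = model
        cont = model.continuous_targets()
        rate = model.rate_targets()
        self.derived_order = _topo_sort_assignments(model)
        self.rate_rules: Dict[str, Expr] = {
            r.target: r.formula for r in model.rules if r.kind == "rate"}
        self.state_symbols: List[str] = [
            sp.id for sp in model.species.values()
            if not sp.boundary and sp.id not in cont and sp.id not in rate]
        self.state_symbols += [r.target for r in model.rules
                               if r.kind == "rate"]
        # reaction-derived stoichiometry map: species -> [(rxn, +/-stoich)]
        self.stoich_map: Dict[str, List[Tuple[str, float, Union[float, str]]]] = {}
        for rxn in model.reactions.values():
            for sign, parts in ((-1.0, rxn.reactants), (1.0, rxn.products)):
                for p in parts:
                    self.stoich_map.setdefault(p.species, []).append(
                        (rxn.id, sign, p.stoichiometry))
        self._cont = cont

    # -- evaluation --------------------------------------------------------
    def _eval(self, expr: Expr, t: float, env: Dict[str, float],
              rng: Optional[RngStream] = None) -> float:
        if isinstance(expr, Num):
            return expr.value
        if isinstance(expr, TimeSym):
            return t
        if isinstance(expr, Sym):
            try:
                return env[expr.name]
            except KeyError:
                raise LanguageError(
                    f"symbol '{expr.name}' has no value") from None
        if isinstance(expr, Unary):
            return -self._eval(expr.child, t, env, rng)
        if isinstance(expr, Binary):
            a = self._eval(expr.left, t, env, rng)
            b = self._eval(expr.right, t, env, rng)
            op = expr.op
            if op == "+":
                return a + b
            if op == "-":
                return a - b
            if op == "*":
                return a * b
            if op == "/":
                return a / b
            if op == "^":
                return a ** b
            # comparators return 1.0 / 0.0
            return float({"<": a < b, ">": a > b, "<=": a <= b,
                          ">=": a >= b, "==": a == b, "!=": a != b}[op])
        if isinstance(expr, Call):
            if expr.callee == "rateOf":
                arg = expr.args[0]
                if not isinstance(arg, Sym):
                    raise LanguageError("rateOf argument must be a symbol")
                return self.rate_component(arg.name, t, env)
            if expr.callee in DISTRIBUTION_NAMES:
                if rng is None:
                    raise LanguageError(
                        f"distribution '{expr.callee}' evaluated outside a "
                        "discrete context")
                args = [self._eval(a, t, env, rng) for a in expr.args]
                return sample_value(expr.callee, args, rng)
            fn = _FUNCS.get(expr.callee)
            if fn is None:
                if expr.callee == "root":
                    args = [self._eval(a, t, env, rng) for a in expr.args]
                    return args[-1] ** (1.0 / args[0]) if len(args) == 2 \
                        else math.sqrt(args[0])
                raise LanguageError(f"unknown function '{expr.callee}'")
            return float(fn(*[self._eval(a, t, env, rng)
                              for a in expr.args]))
        raise LanguageError(f"cannot evaluate {expr!r}")

    def evaluate(self, expr: Expr, t: float, env: Dict[str, float],
                 rng: Optional[RngStream] = None) -> float:
        """Evaluate an expression in a prepared environment."""
        return self._eval(expr, t, env, rng)

    def _apply_derived(self, t: float, env: Dict[str, float]) -> None:
        for target, formula in self.derived_order:
            env[target] = self._eval(formula, t, env)

    def environment(self, t: float, y: Sequence[float],
                    base: Dict[str, float]) -> Dict[str, float]:
        """Full symbol environment at (t, y): base values + state + derived."""
        env = dict(base)
        env.update(zip(self.state_symbols, y))
        self._apply_derived(t, env)
        return env

    def rate_component(self, symbol: str, t: float,
                       env: Dict[str, float]) -> float:
        """d(symbol)/dt at the given environment.

        Species: stoichiometry-weighted sum of reaction rates (zero for
        boundary species) plus nothing else; rate-rule targets: their
        formula.  Reactions and assignment-rule targets are rejected.
        """
        if symbol in self.model.reactions:
            raise LanguageError(
                f"rateOf cannot be applied to reaction '{symbol}'")
        if symbol in self._cont:
            raise LanguageError(
                f"rateOf cannot be applied to assignment-rule target "
                f"'{symbol}'")
        if symbol in self.rate_rules:
            return self._eval(self.rate_rules[symbol], t, env)
        if symbol in self.model.species:
            sp = self.model.species[symbol]
            if sp.boundary:
                return 0.0
            total = 0.0
            for rxn_id, sign, stoich in self.stoich_map.get(symbol, ()):
                kl = self.model.reactions[rxn_id].kinetic_law
                if kl is None:
                    continue
                mult = env[stoich] if isinstance(stoich, str) else stoich
                total += sign * mult * self._eval(kl, t, env)
            return total
        if symbol in self.model.parameters:
            return 0.0
        raise LanguageError(f"unknown symbol '{symbol}'")

    def rhs(self, t: float, y: np.ndarray,
            base: Dict[str, float]) -> np.ndarray:
        env = self.environment(t, y, base)
        return np.array([self.rate_component(s, t, env)
                         for s in self.state_symbols])

    # -- initialization ----------------------------------------------------
    def initial_environment(self, rng: RngStream) -> Dict[str, float]:
        """Evaluate all initial assignments (drawing distributions once).

        Returns values for every species and parameter; assignment-rule
        targets are then derivable.  Uninitialized symbols default to 0.
        """
        m = self.model
        initials: Dict[str, Optional[Expr]] = {}
        for sp in m.species.values():
            initials[sp.id] = sp.initial
        for par in m.parameters.values():
            initials[par.id] = par.initial
        cont = {t for t, _ in self.derived_order}
        env: Dict[str, float] = {}
        resolving: List[str] = []

        def value_of(name: str) -> float:
            if name in env:
                return env[name]
            if name in resolving:
                raise LanguageError(
                    "cyclic initial assignments: " +
                    " -> ".join(resolving + [name]))
            expr = initials.get(name)
            if expr is None:
                env[name] = 0.0
                return 0.0
            resolving.append(name)
            needed = [s for s in expr_symbols(expr)
                      if s in initials and s not in cont]
            for dep in needed:
                value_of(dep)
            local = dict(env)
            resolving.pop()
            env[name] = self._eval(expr, 0.0, local, rng)
            return env[name]

        for name in initials:
            if name not in cont:
                value_of(name)
        self._apply_derived(0.0, env)
        return env


def _topo_sort_assignments(model: Model) -> List[Tuple[str, Expr]]:
    rules = {r.target: r.formula for r in model.rules
             if r.kind == "continuous" and r.target}
    order: List[Tuple[str, Expr]] = []
    state: Dict[str, int] = {}

    def visit(node: str) -> None:
        state[node] = 1
        for dep in expr_symbols(rules[node]):
            if dep in rules:
                if state.get(dep) == 1:
                    raise LanguageError(
                        f"cyclic assignment rules involving '{node}'")
                if state.get(dep, 0) == 0:
                    visit(dep)
        state[node] = 2
        order.append((node, rules[node]))

    for node in rules:
        if state.get(node, 0) == 0:
            visit(node)
    return order


def compile_model(model: Model) -> CompiledSystem:
    """Compile a validated Model for numerical execution."""
    return CompiledSystem(model)


def simulate(sys: CompiledSystem, t_end: float, n_points: int = 101,
             seed: int = 0) -> Trajectory:
    """Integrate the compiled system on a uniform grid.

    Same seed, same trajectory: all distribution draws (initial and
    event-time) come from one seeded stream consumed in a fixed order.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if n_points < 2:
        raise ValueError("n_points must be at least 2")
    rng = RngStream(seed)
    model = sys.model
    env0 = sys.initial_environment(rng)
    # base: every symbol that is not state or derived keeps its env0 value
    derived = {t for t, _ in sys.derived_order}
    base = {k: v for k, v in env0.items()
            if k not in sys.state_symbols and k not in derived}
    y = np.array([env0[s] for s in sys.state_symbols], dtype=float)
    grid = np.linspace(0.0, t_end, n_points)
    recorded = [s for s in list(model.species) + list(model.parameters)]
    out = {s: np.empty(n_points) for s in recorded}
    event_log: List[Tuple[float, str]] = []
    tol = _EVENT_TOL_FACTOR * t_end

    def trigger_state(t: float, yv: np.ndarray) -> List[bool]:
        env = sys.environment(t, yv, base)
        return [sys.evaluate(ev.trigger, t, env) != 0.0
                for ev in model.events]

    def record(i: int, t: float, yv: np.ndarray) -> None:
        env = sys.environment(t, yv, base)
        for s in recorded:
            out[s][i] = env[s]

    armed_false = [not v for v in trigger_state(0.0, y)]
    record(0, 0.0, y)

    for i in range(1, n_points):
        t0, t1 = grid[i - 1], grid[i]
        tc = t0
        while tc < t1 - 1e-15 * t_end:
            if len(sys.state_symbols) == 0:
                sol = None
                t_reached = t1
                y_reached = y
            else:
                res = solve_ivp(sys.rhs, (tc, t1), y, args=(base,),
                                method="LSODA", rtol=RTOL, atol=ATOL,
                                dense_output=True)
                if not res.success:
                    raise LanguageError(
                        f"integration failed at t={res.t[-1]:.6g}: "
                        f"{res.message}")
                sol = res.sol
                t_reached = res.t[-1]
                y_reached = res.y[:, -1]
            fired = _first_event(sys, model, base, armed_false, sol,
                                 tc, t_reached, y, y_reached, tol)
            if fired is None:
                y = np.asarray(y_reached, dtype=float)
                now = trigger_state(t_reached, y)
                for k, v in enumerate(now):
                    if not v:
                        armed_false[k] = True
                tc = t_reached
            else:
                t_ev, y_ev, k = fired
                ev = model.events[k]
                env = sys.environment(t_ev, y_ev, base)
                updates = {target: sys.evaluate(expr, t_ev, env, rng)
                           for target, expr in ev.assignments}
                y = np.asarray(y_ev, dtype=float).copy()
                for target, value in updates.items():
                    if target in sys.state_symbols:
                        y[sys.state_symbols.index(target)] = value
                    else:
                        base[target] = value
                event_log.append((t_ev, ev.id))
                armed_false[k] = False
                now = trigger_state(t_ev, y)
                for j, v in enumerate(now):
                    if not v:
                        armed_false[j] = True
                tc = t_ev
        record(i, t1, y)

    return Trajectory(np.array(grid), out, event_log)


def _first_event(sys: CompiledSystem, model, base, armed_false, sol,
                 t_lo: float, t_hi: float, y_lo, y_hi,
                 tol: float) -> Optional[Tuple[float, np.ndarray, int]]:
    """Earliest armed false->true trigger edge in (t_lo, t_hi], bisected."""
    def value(k: int, t: float, yv) -> bool:
        env = sys.environment(t, yv, base)
        return sys.evaluate(model.events[k].trigger, t, env) != 0.0

    def y_at(t: float):
        if sol is None:
            return y_lo
        return sol(t)

    best: Optional[Tuple[float, np.ndarray, int]] = None
    for k in range(len(model.events)):
        if not armed_false[k]:
            continue
        if not value(k, t_hi, y_hi):
            continue
        lo, hi = t_lo, t_hi
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if value(k, mid, y_at(mid)):
                hi = mid
            else:
                lo = mid
        t_ev = hi
        if best is None or t_ev < best[0]:
            best = (t_ev, np.asarray(y_at(t_ev), dtype=float), k)
    return best


def rate_of(sys: CompiledSystem, symbol: str, t: float,
            state: Union[Dict[str, float], Sequence[float]]) -> float:
    """d(symbol)/dt at an explicit state.

    ``state`` is either a vector aligned with ``sys.state_symbols`` or a
    mapping of symbol values layered over the model's initial values.
    """
    rng = RngStream(0)
    env = sys.initial_environment(rng)
    if isinstance(state, dict):
        env.update(state)
        sys._apply_derived(t, env)
    else:
        env = sys.environment(t, np.asarray(state, dtype=float), env)
    return sys.rate_component(symbol, t, env)
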