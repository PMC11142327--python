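"""Probability-distribution draws and uncertainty annotations.

The language allows a dozen distribution functions in *discrete*
contexts (initial assignments and event assignments).  Each family has
a base signature; most also admit a truncated form with two extra
``min, max`` arguments (``uniform`` and ``bernoulli`` do not).
Truncated draws are produced by rejection sampling.

``lognormal(mean, stdev)`` is parameterized on the log scale: the
arguments are the mean and standard deviation of the *underlying
normal*, so draws are ``exp(N(mean, stdev))``.

Uncertainty statements (``A.mean = 2.4``, ``A.confidenceInterval =
{x, y}``, ``A.distribution is "http://..."``) attach descriptive
statistics to any symbol with mathematical meaning; they have no
effect on simulation and exist to be serialized.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .diagnostics import Diagnostic, LanguageError, Severity, SourceLocation
from .syntax import Call, Expr, Num, Unary, unparse_expr

# family -> arity of the base (untruncated) signature
BASE_ARITY: Dict[str, int] = {
    "normal": 2,
    "uniform": 2,
    "bernoulli": 1,
    "binomial": 2,
    "cauchy": 2,
    "chisquare": 1,
    "exponential": 1,
    "gamma": 2,
    "laplace": 2,
    "lognormal": 2,
    "poisson": 1,
    "rayleigh": 1,
}

# families without a truncated (+2 argument) form
NO_TRUNCATION = {"uniform", "bernoulli"}

DISTRIBUTION_NAMES = frozenset(BASE_ARITY)


def signatures() -> List[Tuple[str, int]]:
    """All accepted (name, arity) pairs — 22 in total."""
    sigs = [(name, k) for name, k in BASE_ARITY.items()]
    sigs += [(name, k + 2) for name, k in BASE_ARITY.items()
             if name not in NO_TRUNCATION]
    return sigs


@dataclass(frozen=True)
class DistributionCall:
    """A validated draw: family name, argument expressions, truncation."""

    name: str
    args: Tuple[Expr, ...]
    truncated: bool

    @property
    def base_args(self) -> Tuple[Expr, ...]:
        return self.args[:-2] if self.truncated else self.args

    @property
    def bounds(self) -> Optional[Tuple[Expr, Expr]]:
        return (self.args[-2], self.args[-1]) if self.truncated else None


def classify(call: Call) -> Optional[DistributionCall]:
    """Interpret a call node as a distribution draw, if the name matches.

    Returns None for non-distribution callees.  Arity is *not* checked
    here; use :func:`validate_distribution`.
    """
    if call.callee not in BASE_ARITY:
        return None
    truncated = len(call.args) == BASE_ARITY[call.callee] + 2 \
        and call.callee not in NO_TRUNCATION
    return DistributionCall(call.callee, tuple(call.args), truncated)


def validate_distribution(call: Union[Call, DistributionCall],
                          loc: Optional[SourceLocation] = None
                          ) -> List[Diagnostic]:
    """Check name and arity against the distribution table."""
    name = call.name if isinstance(call, DistributionCall) else call.callee
    nargs = len(call.args)
    diags: List[Diagnostic] = []
    if name not in BASE_ARITY:
        diags.append(Diagnostic(
            Severity.ERROR, f"unknown distribution '{name}'", loc))
        return diags
    base = BASE_ARITY[name]
    allowed = {base} if name in NO_TRUNCATION else {base, base + 2}
    if nargs not in allowed:
        want = " or ".join(str(a) for a in sorted(allowed))
        diags.append(Diagnostic(
            Severity.ERROR,
            f"'{name}' takes {want} arguments, got {nargs}", loc))
        return diags
    if nargs == base + 2:
        lo, hi = call.args[-2], call.args[-1]
        lo_v, hi_v = _as_number(lo), _as_number(hi)
        if lo_v is not None and hi_v is not None and not lo_v < hi_v:
            diags.append(Diagnostic(
                Severity.ERROR,
                f"truncation bounds of '{name}' require min < max", loc))
    return diags


def _as_number(expr: Expr) -> Optional[float]:
    if isinstance(expr, Num):
        return expr.value
    if isinstance(expr, Unary) and expr.op == "-" and isinstance(expr.child, Num):
        return -expr.child.value
    return None


# --------------------------------------------------------------------------
# Sampling
# --------------------------------------------------------------------------


@dataclass
class RngStream:
    """Seeded PCG64 stream; equal seeds give equal draw sequences."""

    seed: int
    algorithm: str = "pcg64"
    _gen: np.random.Generator = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._gen = np.random.Generator(np.random.PCG64(self.seed))

    @property
    def generator(self) -> np.random.Generator:
        return self._gen


class SamplingError(LanguageError):
    """Invalid parameter domain or exhausted truncation rejection loop."""


_REJECTION_CAP = 10 ** 6


def sample_value(name: str, args: Sequence[float], rng: RngStream) -> float:
    """One draw from the named family with numeric arguments.

    Truncated forms (two trailing ``min, max`` arguments) are sampled by
    rejection with an iteration cap; discrete families (bernoulli,
    binomial, poisson) return integer-valued floats.
    """
    base = BASE_ARITY.get(name)
    if base is None:
        raise SamplingError(f"unknown distribution '{name}'")
    if len(args) == base:
        return _draw(name, list(args), rng.generator)
    if len(args) == base + 2 and name not in NO_TRUNCATION:
        lo, hi = args[-2], args[-1]
        if not lo < hi:
            raise SamplingError(
                f"truncation bounds of '{name}' require min < max")
        for _ in range(_REJECTION_CAP):
            x = _draw(name, list(args[:-2]), rng.generator)
            if lo <= x <= hi:
                return x
        raise SamplingError(
            f"rejection sampling for truncated '{name}' exceeded "
            f"{_REJECTION_CAP} iterations")
    raise SamplingError(f"'{name}' does not take {len(args)} arguments")


def sample(call: DistributionCall, rng: RngStream) -> float:
    """Draw from a call whose arguments are numeric literals."""
    vals = []
    for a in call.args:
        v = _as_number(a)
        if v is None:
            raise SamplingError(
                f"non-numeric argument to '{call.name}': {unparse_expr(a)}")
        vals.append(v)
    return sample_value(call.name, vals, rng)


def _draw(name: str, a: List[float], g: np.random.Generator) -> float:
    if name == "normal":
        mean, sd = a
        if sd < 0:
            raise SamplingError("normal stddev must be >= 0")
        return mean if sd == 0 else float(g.normal(mean, sd))
    if name == "uniform":
        lo, hi = a
        if lo > hi:
            raise SamplingError("uniform requires min <= max")
        return float(g.uniform(lo, hi))
    if name == "bernoulli":
        (p,) = a
        if not 0 <= p <= 1:
            raise SamplingError("bernoulli probability must be in [0, 1]")
        return float(g.random() < p)
    if name == "binomial":
        n, p = a
        if n < 0 or n != int(n):
            raise SamplingError("binomial nTrials must be a non-negative integer")
        if not 0 <= p <= 1:
            raise SamplingError("binomial probability must be in [0, 1]")
        return float(g.binomial(int(n), p))
    if name == "cauchy":
        loc, scale = a
        if scale < 0:
            raise SamplingError("cauchy scale must be >= 0")
        return loc if scale == 0 else float(loc + scale * g.standard_cauchy())
    if name == "chisquare":
        (df,) = a
        if df <= 0:
            raise SamplingError("chisquare degreesOfFreedom must be > 0")
        return float(g.chisquare(df))
    if name == "exponential":
        (rate,) = a
        if rate <= 0:
            raise SamplingError("exponential rate must be > 0")
        return float(g.exponential(1.0 / rate))
    if name == "gamma":
        shape, scale = a
        if shape <= 0 or scale <= 0:
            raise SamplingError("gamma shape and scale must be > 0")
        return float(g.gamma(shape, scale))
    if name == "laplace":
        loc, scale = a
        if scale < 0:
            raise SamplingError("laplace scale must be >= 0")
        return loc if scale == 0 else float(g.laplace(loc, scale))
    if name == "lognormal":
        mean, sd = a
        if sd < 0:
            raise SamplingError("lognormal stdev must be >= 0")
        return float(np.exp(mean)) if sd == 0 else float(g.lognormal(mean, sd))
    if name == "poisson":
        (rate,) = a
        if rate < 0:
            raise SamplingError("poisson rate must be >= 0")
        return float(g.poisson(rate))
    if name == "rayleigh":
        (scale,) = a
        if scale < 0:
            raise SamplingError("rayleigh scale must be >= 0")
        return 0.0 if scale == 0 else float(g.rayleigh(scale))
    raise SamplingError(f"unknown distribution '{name}'")


# --------------------------------------------------------------------------
# Uncertainty records
# --------------------------------------------------------------------------

# canonical attribute name -> accepted spellings
SCALAR_ATTRIBUTES = ("mean", "stdev", "coefficientOfVariation", "kurtosis",
                     "median", "mode", "sampleSize", "skewness",
                     "standardError", "variance")
INTERVAL_ATTRIBUTES = ("confidenceInterval", "credibleInterval",
                       "interquartileRange", "range")
_ALIASES = {"standardDeviation": "stdev"}


def canonical_attribute(name: str) -> Optional[str]:
    name = _ALIASES.get(name, name)
    if name in SCALAR_ATTRIBUTES or name in INTERVAL_ATTRIBUTES:
        return name
    if name in ("distribution", "externalParameter"):
        return name
    return None


@dataclass
class UncertaintyRecord:
    """Per-symbol uncertainty attributes, mirrored into SBML on export."""

    scalars: Dict[str, Expr] = field(default_factory=dict)
    intervals: Dict[str, Tuple[Expr, Expr]] = field(default_factory=dict)
    distribution: Optional[Union[Expr, str]] = None   # formula or URI
    external_parameter: Optional[Union[Expr, Tuple[Expr, Expr], str]] = None

    def is_empty(self) -> bool:
        return not (self.scalars or self.intervals
                    or self.distribution is not None
                    or self.external_parameter is not None)
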