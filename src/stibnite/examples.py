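"""Bundled example models, one per core language capability.

These are the canonical small models used throughout the tests and the
documentation: mass-action reactions, branched pathways, non-unity and
symbolic stoichiometries, boundary species, forcing functions, rate
rules, metadata blocks, rateOf, distribution draws in events,
uncertainty attributes, flux-balance constraints and algebraic rules.

Two fixtures are normalizations rather than verbatim models:

* ``listing10`` concretizes the uncertainty syntax table (placeholders
  ``x``, ``y``, ``function()`` and ``"http://uri"`` become declared
  symbols, a ``normal`` draw and an example.org URI);
* ``listing11`` adds a minimal three-reaction network so the flux
  symbols referenced by the objective and constraints resolve.
"""
from __future__ import annotations

from typing import Dict, List

LISTINGS: Dict[str, str] = {}

LISTINGS["listing01"] = """\
// Define a single reaction with reactant A and product B and rate law k1*A
A -> B; k1*A
// Initialize values
A = 5
B = 0
k1 = 0.1
"""

LISTINGS["listing02"] = """\
// Define three reactions forming a simple branch
A -> B; k1*A
B -> C; k2*B
B -> D; k3*B - k4*C
// Initialize values
A = 5; B = 0; C = 0; D = 0;
k1 = 0.1; k2 = 0.2; k3 = 0.15; k4 = 3.4
"""

LISTINGS["listing03"] = """\
// A reaction with multiple reactants
A + B -> C; k1*A*B
// A reaction with non-unity stoichiometry
2 C -> D + E; k2*C
// Initialize values
A = 5; B = 0; C = 0; D = 0; E = 0; k1 = 0.1; k2 = 0.2;
"""

LISTINGS["listing04"] = """\
// Name a reaction 'J1'.
J1: A + B -> C; k1*A*B
// Initialize values
A = 5; B = 2; C = 0; k1 = 0.1;
"""

LISTINGS["listing05"] = """\
// A reaction with an external reactant, A, indicated with a dollar symbol.
// Species A will be fixed in any model generated from this script
$A -> B; k1*A
// A reaction with a forcing function. In this case, the function
// is a sine wave of a given frequency and amplitude. Note the use of
// the ':=' assignment symbol to indicate this equation is part of the model
// and will be executed continuously when the model is simulated
X := 1 + amp*sin (time*freq)
$X -> Y; k1*X
// Initialize values
A = 1
amp = 2.5; freq = 0.5; k1 = 0.1;
"""

LISTINGS["listing06"] = """\
// Define a reaction.
J1: $A + B -> C; k1*A*B
// The 'A' species here is not consumed by reaction J1, and instead increases
// at an autocatalytic rate
$A' = k2 * A
// Initialize values
A = 5; B = 2; C = 0; k1 = 0.1; k2 = 0.01
"""

LISTINGS["listing07"] = """\
model mymodel()
S1 -> S2; k1*S1
model notes "This is a small model"
end
"""

LISTINGS["listing08"] = """\
J0: S0 -> S1; k0*S0
J1: S1 -> S2; k1*S1
X1 := rateOf(S1)
C' = 10*k3
X2 := rateOf(C)
"""

LISTINGS["listing09"] = """\
J0: S0 -> S1; k0*S0
J1: S1 -> S2; k1*S1
if S1 > 10:
  k0 = uniform(2.5, 5.5)
S0 = normal(0.5, 0.2)
S1 = normal(0.5, 0.2)
S2 = 0
"""

LISTINGS["listing10"] = """\
// Uncertainty attributes attached to a quantity A.
// Concretized syntax table: x and y are declared symbols, the formula
// form uses a normal draw and the URI form an example.org address.
A = 1
x = 2.4
y = 8.2
A.mean = x
A.stdev = x
A.coefficientOfVariation = x
A.kurtosis = x
A.median = x
A.mode = x
A.sampleSize = x
A.skewness = x
A.standardError = x
A.variance = x
A.confidenceInterval = {x, y}
A.credibleInterval = {x, y}
A.interquartileRange = {x, y}
A.range = {x, y}
A.distribution = normal(x, y)
A.externalParameter is "http://example.org/parameter"
"""

LISTINGS["listing11"] = """\
// Minimal reaction network so the flux symbols resolve
R16: A -> B
R03: B -> C
R02: C -> A
// The objective function (for FBC analysis):
OBJF: maximize R16 + R03;
// Constraints:
constraint c0: R16 >= 0
constraint c1: R16 <= 1000
constraint c2: R03 >= -1000
constraint c3: R03 <= 1000
constraint c4: R02 >= -1000
constraint c5: R02 <= 1000
"""

LISTINGS["listing12"] = """\
J0: S0 -> S1; k0*S0
J1: n S1 -> m S2; k1*S1^n
n := k2/2
m = 2/3
"""

LISTINGS["listing13"] = """\
0 = S1*k1 - 10
alg2: 0 = S2*k2 - 20
"""

LISTING_NAMES: List[str] = sorted(LISTINGS)

#: listings the ODE engine can execute (no algebraic rules)
SIMULATABLE = [n for n in LISTING_NAMES if n != "listing13"]
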