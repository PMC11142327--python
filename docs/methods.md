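# Methods

This note records the semantics the package implements, the numerical
choices behind them, and what the bundled examples do and do not
demonstrate.

## Language model

A model is a flat statement sequence; statements are separated by
newlines or `;`, with `//` comments. Typographic characters that
appear when model text passes through word processors or typesetting
(U+2212 minus, en/em dashes, curly quotes and apostrophes) are
normalized to ASCII before lexing, so `A −> B` and `A -> B` are the
same program.

**Classification.** Identifiers that appear in a reaction participant
list are species; identifiers seen only in formulas or assignments are
parameters; reaction labels name reactions (unnamed reactions get
`_J0, _J1, …` in source order). Symbolic stoichiometries (`n S1`)
declare parameters. A single implicit compartment
`default_compartment` of size 1 owns all species, so amounts and
concentrations coincide; the language itself never mentions
compartments.

**Boundary species.** `$` marks a species whose amount reactions do
not change. A species that participates in reactions *and* is the
target of a rate rule or an assignment rule must carry `$`; otherwise
the reaction ODE and the rule would both claim its derivative, and the
builder reports an error rather than guessing.

**Defaults and conflicts.** Uninitialized symbols default to 0 with a
warning (fail-soft keeps fragmentary models loadable). Duplicate
initializations: last statement wins, with a warning. A symbol may
have at most one assignment rule or one rate rule, never both.
Metadata statements are only legal inside an explicit
`model name() … end` block; creator indices must be contiguous from 1
(a sparse `creator2` with no `creator1` is an error, not a silent
hole).

**Reversibility.** Reactions written `->` are exported with
`reversible="true"`. SBML L3 has no default for the flag and the
dialect has no separate reversible/irreversible arrow; rate laws with
explicit backward terms (e.g. `k3*B - k4*C`) argue against forcing
irreversibility. Directionality, where it matters, is carried by the
rate law or by FBC bounds.

**Events.** The event body is the maximal run of statements indented
further than the `if` line — indentation is the only thing separating
the body from subsequent top-level statements.

**Open-ended cases decided here.** Reactions may omit a kinetic law
(constraint-based models have none). Whether `constraint` statements
may bound non-reaction symbols was open; they are restricted to
reactions, matching FBC. Uncertainty may attach to any declared
symbol with mathematical meaning; attaching to an undeclared one
auto-declares a parameter with a warning.

## Distributions and uncertainty

Twelve families are accepted; each has a base signature and, except
`uniform` and `bernoulli`, a truncated form with two extra
`min, max` arguments — 22 signatures total, enforced exactly.
Truncation is by rejection sampling with a 10⁶-iteration cap, uniform
across families; degenerate widths (`normal(m, 0)`) return the
location exactly. Discrete families return integer-valued reals,
since symbols hold reals. `lognormal(mean, stdev)` is parameterized
on the log scale (the underlying normal), following the SBML
Distributions convention. `cauchy`/`laplace`/`rayleigh` reject
negative scale. Draws come from a seeded PCG64 stream; equal seeds
give equal sequences.

Draws are legal only in *discrete* contexts — initial assignments and
event assignments. In kinetic laws, assignment/rate/algebraic rules
they are errors: a quantity resampled at every evaluation has no ODE
semantics.

Uncertainty attributes (ten scalars, four interval pairs,
`distribution`, `externalParameter`) are descriptive only; they never
affect simulation and exist to be serialized. `standardDeviation`
aliases `stdev`.

## SBML translation

Export targets Level 3 Version 2 core, FBC **version 1** (flux bounds
+ linear objectives; `fbc:required="false"`) and the Distributions
package (`distrib:required="true"`, as draws change math semantics).
The metadata→RDF qualifier table (`model_source` → `bqmodel:is`,
`publication` → `bqmodel:isDescribedBy`, `biological_system` →
`bqbiol:is`, `taxon` → `bqbiol:hasTaxon`, creators → vCard, timestamps
→ W3CDTF, notes → XHTML) is a fixed convention of this package
mirroring BioModels curation practice; the language names the
keywords but not their qualifiers.

Symbolic stoichiometries export as `speciesReference` ids plus an
`initialAssignment` (for `=`) or `assignmentRule` (for `:=`) targeting
that id — no shadow parameter is emitted, since SIds share one
namespace. MathML uses `<ci>`, `<cn>`, `<csymbol>` for `time` and
`rateOf`, and the Distributions csymbol URIs for draws; `^` maps to
`<power/>`. `log` means base 10 (`ln` is natural), so `log10`
canonicalizes to `log` on a round trip.

Serialization is canonical — fixed element and attribute order, the
same decimal rendering as the text unparser — which is what makes
`export ∘ import ∘ export` a byte-level fixed point. Import accepts
the emitted subset and degrades politely elsewhere: function/unit
definitions and event delays/priorities are dropped with warnings; an
FBC namespace other than v1, or an unknown required package, is an
error. Documents are checked structurally (SId syntax, id uniqueness,
compartment references); no external schema validator is invoked.

One asymmetry: a species that appears in no reaction cannot be
re-declared as a species in the text dialect (species-hood comes from
participant lists), so such an imported species would come back as a
parameter. The construct does not occur in models this package
writes.

## Execution engine

State vector: non-boundary, non-rule-assigned species plus rate-rule
targets, in declaration order. Assignment-rule targets are derived
quantities recomputed from the state at every right-hand-side call, in
topological order (cycles are a compile error); symbolic
stoichiometries are therefore re-read instantaneously each call.
Algebraic rules are declined at compile time — they serialize fine,
but this engine solves ODEs, not DAEs, and refusing is better than a
wrong answer.

Integration: `scipy.integrate.solve_ivp` with LSODA (stiff-capable),
`rtol 1e-8`, `atol 1e-12` — tight enough that closed-form checks at
1e-6 relative are meaningful. Simulations run segment-by-segment
between output grid points.

Events: triggers are edge-detected (false → true) at segment
boundaries and the crossing is localized by bisection on the dense
solution to `1e-9·t_end`; assignments evaluate against the pre-event
state and apply atomically in listed order. A trigger must return to
false before it can fire again, and a trigger already true at t = 0
does not fire (`initialValue="true"` on export). A trigger excursion
contained strictly inside one integration segment can be missed; the
output grid bounds the detection resolution.

Randomness: one seeded stream per simulation, consumed in a fixed
order — initial-assignment draws once at t = 0, event-assignment draws
at firing time — so equal seeds reproduce trajectories and event logs
bit-for-bit.

`rateOf(x)` is the RHS component of x: stoichiometry-weighted reaction
rates for a species (zero for boundary species), the rule formula for
a rate-rule target, zero for a constant parameter; reactions and
assignment-rule targets are rejected, matching the validator.

## Bundled examples and what they show

The 13 bundled models (`stibnite.examples`) are small canonical
programs, one per capability, used as fixtures throughout; two are
normalizations (the uncertainty table concretized with declared
symbols and an example URI; the flux-constraint example given a
minimal 3-reaction network so its flux symbols resolve). They
exercise every language construct, but they are desk-scale: a handful
of species, non-stiff rate constants, single events. Passing tests on
them demonstrates the language semantics and the translation
contract — not performance or robustness on large curated models,
multi-compartment physiology, or stiff oscillators.

Problem sizes used by the verification suite: 101-point grids over
t ∈ [0, 10–20] for ODE checks, 10³–10⁵ draws for sampling statistics
(the CLT band for the 10⁵-draw mean check is 3σ/√n ≈ 0.0019), all 720
permutations (subsampled) for bounds-table order independence.

## Known limitations

* No hierarchical model composition, unit definitions, user-defined
  functions, or layout/render support.
* No DAE solving; no stochastic (Gillespie) simulation; no LP solver
  for FBC (encoding and bounds folding are the deliverables).
* `at`-style events, delays and priorities are not part of the
  dialect; imported SBML delays/priorities are dropped with warnings.
* Import preserves model order for the emitted subset; exotic SBML
  (multiple compartments, conversion factors, persistent=false
  triggers) is outside the supported profile.
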