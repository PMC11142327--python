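"""Query instantaneous rates of change with rateOf.

rateOf(x) is the time derivative the integrator would use: for a
species it is the stoichiometry-weighted sum of reaction rates, for a
rate-rule target it is the rule's right-hand side.  Applying it to a
reaction id or to an assignment-rule target is a language error, which
the validator reports.
"""
from stibnite import check_rateof_usage, compile_model, loads, rate_of

MODEL = """\
J0: S0 -> S1; k0*S0
J1: S1 -> S2; k1*S1
X1 := rateOf(S1)
C' = 10*k3
X2 := rateOf(C)
S0 = 5; S1 = 2; S2 = 0; k0 = 0.8; k1 = 0.3; k3 = 0.5
"""

model = loads(MODEL)
system = compile_model(model)
state = {"S0": 5.0, "S1": 2.0, "k0": 0.8, "k1": 0.3, "k3": 0.5}
print(f"rateOf(S1) = {rate_of(system, 'S1', 0.0, state):.3f}   "
      "(= k0*S0 - k1*S1 = 0.8*5 - 0.3*2)")
print(f"rateOf(C)  = {rate_of(system, 'C', 0.0, state):.3f}   "
      "(= 10*k3 = 10*0.5)")

bad = loads("J0: A -> B; k*A\nX := rateOf(J0)\nA = 1\nk = 0.1\n")
for diag in check_rateof_usage(bad):
    print(f"diagnostic: {diag.message}")
print("Species and rate-rule targets are differentiable; reactions and "
      "assignment targets are not.")
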