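"""Parse a one-reaction mass-action model and integrate it.

The model is A -> B with rate k1*A, so A(t) = A0 * exp(-k1 t) exactly;
the printed maximum relative error shows how closely the ODE engine
tracks the closed form, and the conservation defect checks that the
stoichiometry bookkeeping preserves total mass A + B.
"""
import numpy as np

from stibnite import compile_model, loads, simulate

MODEL = """\
A -> B; k1*A
A = 5
B = 0
k1 = 0.1
"""

model = loads(MODEL)
system = compile_model(model)
traj = simulate(system, t_end=10.0, n_points=101, seed=0)

exact = 5.0 * np.exp(-0.1 * traj.time)
print(f"A(10)                = {traj['A'][-1]:.6f}  (exact {exact[-1]:.6f})")
print(f"max relative error   = {np.max(np.abs(traj['A'] - exact) / exact):.2e}")
print(f"max |A + B - 5|      = {np.max(np.abs(traj['A'] + traj['B'] - 5)):.2e}")
print("A decays exponentially at rate k1; mass moves to B without loss.")
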