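"""Lumping a Michaelis-Menten biosynthesis pathway.

The six-step chain-elongation pathway of aliphatic glucosinolate
biosynthesis is reduced to its first conversion plus one delayed
completion whose delay uses a harmonic-mean effective Michaelis-Menten
rate.  A constant-delay baseline shows why state dependence matters.
"""
import numpy as np

from sdssa import build_glucosinolate, ensemble_mean, run

grid = np.linspace(0.0, 1.2e7, 13)
reps = 150

full = ensemble_mean(build_glucosinolate(100, reduced="full"), 1.2e7, grid,
                     reps=reps, seed=7,
                     species=tuple(f"E{i}" for i in range(1, 7)))
state = ensemble_mean(build_glucosinolate(100, reduced="state"), 1.2e7,
                      grid, reps=reps, seed=8, species=("E1", "U"))
const = ensemble_mean(build_glucosinolate(100, reduced="constant"), 1.2e7,
                      grid, reps=reps, seed=9, species=("E1", "U"))

print(f"{'t':>10} {'full 6-step':>12} {'state delay':>12} {'const delay':>12}")
for t, f, s, c in zip(grid, full.total(), state.total(), const.total()):
    print(f"{t:10.2e} {f:12.2f} {s:12.2f} {c:12.2f}")

print("\nThe state-dependent reduction tracks the full pathway throughout; "
      "the constant delay (3e6) keeps all 100 molecules frozen until its "
      "deadline and then collapses far too quickly.")
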