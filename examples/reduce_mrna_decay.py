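"""Reducing nine-step mRNA decay to a single delayed reaction.

The decay of RPL30 transcripts -- eight poly(A)-shortening steps plus a
terminal deadenylation -- is replaced by one consuming reaction and one
nonconsuming completion whose delay is recomputed from the current state.
The ensemble mean of the reduced model is compared with the full chain.
"""
import numpy as np

from sdssa import (ChainSpec, build_rpl30, ensemble_mean, ensemble_total)

k, s0, reps = 0.126, 100, 300
grid = np.linspace(0.0, 150.0, 16)

chain_mean, _ = ensemble_total(ChainSpec(n=9, k=k, x10=s0, y0=0),
                               grid, reps=reps, seed=5)
reduced = build_rpl30(s0=s0, y0=0, k=k)
red = ensemble_mean(reduced, 150.0, grid, reps=reps, seed=6,
                    species=("X1", "G"))

print(f"{'t (min)':>8} {'9-step chain':>13} {'reduced model':>14}")
for t, c, r in zip(grid, chain_mean, red.total()):
    print(f"{t:8.0f} {c:13.2f} {r:14.2f}")

rms = np.sqrt(np.mean((red.total() - chain_mean) ** 2)) / s0
print(f"\nRMS difference: {100 * rms:.1f}% of the initial count.")
print("Two reactions with a state-dependent delay reproduce the sigmoidal "
      "mean decay of the nine-reaction chain; a single exponential (or a "
      "constant delay) cannot produce this shape.")
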