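"""Three equivalent views of a multistep decay chain.

Builds a 3-step chain with 20 molecules in the first state, then compares
the closed-form expected total count, numerical ODE integration, and the
mean of 2000 exact SSA realizations at a few time points.
"""
import numpy as np

from sdssa import ChainSpec, analytic_total, ensemble_total, ode_totals

chain = ChainSpec(n=3, k=1.0, x10=20, y0=0)
grid = np.linspace(0.5, 8.0, 6)

exact = analytic_total(chain, grid)
ode = ode_totals(chain, np.concatenate(([0.0], grid)))[1:]
mean, se = ensemble_total(chain, grid, reps=2000, seed=1)

print(f"{'t':>5} {'closed form':>12} {'ODE':>12} {'SSA mean':>10} {'SE':>7}")
for t, e, o, m, s in zip(grid, exact, ode, mean, se):
    print(f"{t:5.1f} {e:12.4f} {o:12.4f} {m:10.4f} {s:7.4f}")

print("\nThe three columns agree: the closed form and the ODE are the same "
      "curve to integrator precision, and the SSA mean fluctuates around "
      "them within a few standard errors -- the chain simulators can serve "
      "as ground truth for any reduced model.")
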