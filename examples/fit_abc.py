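"""Fitting the reduced decay model to (synthetic) observations by ABC.

Generates a sparse decay curve from known ground-truth parameters, then
runs ABC rejection sampling over (k, y0, D) and reports the minimal-error
estimate.  A small run for illustration; the full-scale recovery lives in
the acceptance suite.
"""
import numpy as np

from sdssa import Prior, abc_rejection, build_rpl30, synth_decay_data

truth = dict(s0=100, y0=23, k=0.126, D=1.7184)
times = np.linspace(5.0, 75.0, 8)
data = synth_decay_data(build_rpl30, truth, times, reps=400, seed=11,
                        observables=("X1", "G"))
print("synthetic observations (time, total mRNA):")
print(data.round(2).to_string(index=False))

priors = Prior(bounds={"k": (0.01, 1.0), "y0": (0, 50), "D": (1.0001, 3.0)},
               integer=("y0",))
post = abc_rejection(lambda k, y0, D: build_rpl30(100, int(y0), k, D),
                     priors, data, n_draws=200, keep=20, reps_per_draw=20,
                     seed=12, observables=("X1", "G"))

best = post.best
print(f"\nbest of 200 draws: k = {best['k']:.4f} (truth {truth['k']}), "
      f"y0 = {best['y0']:.0f} (truth {truth['y0']}), "
      f"D = {best['D']:.3f} (truth {truth['D']})")
print(f"summed absolute error at the 8 time points: {best['error']:.1f}")
print("The decay rate k is well identified by the curve; y0 and D mostly "
      "shape the early shoulder and are correspondingly looser.")
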