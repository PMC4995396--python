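# Methods

## Model

The object being reduced is a linear chain of first-order conversions
X1 → X2 → … → Xn → P with equal per-step rate k.  Its expected total count
(product excluded), with x10 molecules in X1 and y0 spread over the
intermediates, is

    s(t) = e^(−kt) [ x10 · Σ_{j<n} (kt)^j/j!
                     + y0 · Σ_{j≤n−2} (n−1−j)/(n−1) · (kt)^j/j! ],

the Erlang survival series for the X1-seeded part plus the uniformly
partitioned intermediate contribution.  In stochastic initial conditions
the y0 intermediates are placed with non-increasing counts differing by at
most one (`initial_partition`); deterministically each holds y0/(n−1).

The reduced model replaces states 2…n by one imaginary species G.  When
the consuming reaction fires at state (x1, y), its completion is defined
as the first time the total count reaches x1 − 1, i.e. the y molecules
queued ahead plus the new one have all converted.  The completion time τ2
solves s(τ2) = x1 − 1 with the current state as initial condition.
Truncating the exponential series with a Lagrange remainder evaluated at
the midpoint ξ = τ2/2 turns that crossing into

    C1 · z^n e^(−z/2) / n! = 1 + C2·y,       z = k·τ2,
    C1 = x1 − y/(n−1),   C2(exact) = 1 − z/(n−1),

solved in closed form: z = −2n·W0(−C^(1/n)/(2n)) with
C = (1 + C2·y)·n!/C1.  The equation has two positive roots (either side of
z = 2n); the first crossing of the decaying total is the smaller one,
hence the principal branch W0.  Two degenerate branches: y = 0 gives
C = n!/x1 directly, and C1 = 0 forces 1 + C2·y = 0, i.e.
τ2 = (n−1)(1 + 1/y)/k with the exact C2.

## The C2 approximation

The exact C2 contains τ2 itself, so simulations use a fitted state-only
stand-in.  We computed the *optimal* C2 — the value that makes the closed
form reproduce the measured mean delay — over a grid of states by
simulation and by the exact crossing of s(t), and fitted the two-parameter
family

    C2(y; α, β) = α (1 + 1/y)(1 − y/β) − 1/y .

Properties: strictly decreasing in y; diverges like α/y as y → 0 (as the
optimal C2 does); equals −1/y exactly at y = β.  The last point matters:
on the locus C1 = 0 (y = (n−1)·x1) the delay equation itself forces
C2 = −1/y, so β estimates that locus.  The calibrated hyper-laws are

    α(x1) = 3.25 + 7.5/x1,        β(x1) = 11.8 + 8.2·x1,

fitted on a nine-step chain (β's slope 8.2 ≈ n−1 = 8 is the locus slope);
for other chain lengths β is rescaled by (n−1)/8.  Refitting the family to
freshly simulated delays (the `calibration` module, which this package can
re-run end to end) yields α ≈ 3.2 + 12/x1, β ≈ −12 + 7.0·x1 — the same
structure with modest coefficient shifts; the published defaults are kept.
Errors in C2 are damped through C^(1/n), so delay errors are roughly n
times smaller than C2 errors.

Numerical choices: C and n! are handled in log space (factorials overflow
double precision near n = 171; log space is used throughout, so large n is
safe); the Lambert argument must stay above −1/e, otherwise a
`DelayDomainError` is raised.  Inside simulations `tau2_robust` catches
that error — the fitted C2 becomes infeasible in a strip between the
C1 = 0 locus and β, and deep in the overloaded regime — and falls back to
bracketed root-finding of the exact series crossing.  For x1 = 1 the
literal threshold x1 − 1 = 0 is reached only asymptotically by the mean
total, so the fallback floors the threshold at half a molecule.  The delay
pushed to the queue is τ = max(τ2 − τ1, 10⁻⁹) where τ1 is the SSA waiting
time of the firing (the completion is anchored at the time the state was
observed); the tiny floor keeps completions strictly after firings.
An optional validation mode solves the equation with the exact
τ2-dependent C2 by root-finding; an optional stochastic mode replaces the
deterministic τ2 by an Erlang(n−1) sample of the same mean, mirroring the
n−1 lumped steps.  Both are off by default (the deterministic fitted form
measured best against the full chain).

## The simulation engine

`sd_ssa` is a rejection delay-SSA.  Channels carry a consuming
stoichiometry ν (applied at firing) and a manifesting stoichiometry u
(applied at completion); each delayed channel routes through exactly one
imaginary species whose count always equals its queued completions (a
checked invariant).  Per step: compute propensities (mass action,
Michaelis–Menten, or an explicit function of time), draw the exponential
waiting time μ; if the earliest queued completion precedes t + μ, advance
to it, apply u, and discard μ (propensities are recomputed next step —
the rejection approximation); otherwise pick the channel by the
categorical rule, apply ν, and, if delayed, schedule the completion.
State-dependent delays are evaluated from the state immediately *before*
ν is applied, so x1 still counts the firing molecule and y the pre-firing
queue.  A queued completion wins ties with the drawn firing (measure-zero
event, deterministic ordering).  Time-varying propensities are treated as
piecewise constant between events; for such systems the step size is
capped (default t_end/2000) so rates are re-evaluated on that resolution,
and quiescent phases are probed forward at the same resolution — adequate
when the driving profile varies slowly against the event rate, which holds
for the cell-cycle pulse used here.  Deterministic τ2 values are memoized
per system and state, which makes ensemble runs cheap.

## Case studies

**mRNA decay (RPL30).**  Nine steps (eight poly(A)-shortenings plus
terminal deadenylation), defaults k = 0.1260 min⁻¹, y0 = 23 of s0 = 100
transcripts already in the shortening phase, D = 1.7184.  The y0 initial
imaginary molecules are pre-scheduled uniformly on [0, MT] with
MT = delay(x10, y0, k, n)/D — partially shortened transcripts finish
within a window about 1/D ≈ 58% of the full state-dependent delay.  When
s0 is changed, y0 defaults to the same 23% fraction.

**SWI5 expression.**  Transcription fires at a·P/(b + P) where P is the
NDD1 activator profile, gated to zero after minute 49 of each cell cycle;
elongation and nuclear export are constant delays (defaults 46.665 and
0.733 min); cytosolic decay is the nine-step state-dependent reduction
with k3 = 1.297 min⁻¹.  The single-cell NDD1 profile is not distributed
with the package, so a synthetic raised-cosine pulse (amplitude 10, peak
at minute 25, width 30, cycle 75 min — the cycle length and amplitude are
modelling choices, injectable) stands in for it.  The transcription-rate
form a·P/(b+P) is likewise injectable.

**Glucosinolate pathway.**  Six Michaelis–Menten conversions with the
published molecule-number parameters (V₁…V₆, K₁…K₆ at an assumed 4·10⁻¹⁴ L
cell; the printed values are taken as authoritative rather than recomputed
from the concentration conversion, which is internally inconsistent).  The
reduction keeps the first conversion and lumps steps 2–6.  The effective
per-molecule rate fed to the delay formula is the harmonic mean of the
per-step rates V_i/(K_i + U/5) — equivalently V̄/(K̄_w + U/5) with V̄ the
harmonic mean of the V_i and K̄_w = V̄·mean(K_i/V_i) a rate-weighted
effective K.  The harmonic mean is the choice that preserves the summed
passage time through the steps; lumping with the plain harmonic mean of
the K_i instead slows the reduced pathway by ~1.5× and visibly breaks the
full-vs-reduced agreement.  A constant-delay baseline (τ = 3·10⁶) is
provided for comparison.

## Inference

`abc_inference` is plain ABC rejection: uniform box priors (defaults
k ∈ [0.01, 1], y0 ∈ {0…s0/2}, D ∈ [1, 3] — weakly informative boxes, the
study that motivated them states none), ensemble-mean simulation per draw,
summed absolute error at the observation times (nucleus and cytosol errors
add for two-compartment data), keep the 150 best draws, report the
minimal-error vector.  The synthetic-data generator emulates the published
decay measurements: ensemble-mean counts of a known ground-truth model at
a handful of time points, optional additive Gaussian noise.  What it does
not emulate: biological replicate-to-replicate variability, measurement
bias of specific assays, and non-stationary transcription leakage — so
passing recovery tests shows identifiability under the model, not
robustness to real-data misspecification.

## Problem sizes and validation scope

The test suite uses 1000-replicate ensembles for fidelity and delay
monotonicity checks (10,000 for the SSA-vs-closed-form oracle), an
8-point synthetic decay curve from 1000-replicate means, and ABC with
2000 draws × 30 replicates per draw (the acceptance script uses 600-rep
ensembles and 25 replicates per draw; E1 = 2000 pathway runs use 100–200
replicates).  Tolerances: closed form vs bisection 10⁻⁸ relative;
analytic vs ODE totals 10⁻⁶ relative; Monte-Carlo comparisons three
standard errors; reduced-vs-full fidelity 5% RMS of the initial count
over the decay window; ABC recovery of k within 20%.

## Known limitations

* A state-(x1, y) delay cannot see the *age distribution* of in-transit
  molecules.  During the filling phase of a pure-decay run (X1 drains at
  rate k while passage takes (n−1)/k) the intermediates bunch in early
  states and true delays run ~10% longer than the calibrated formula; the
  nine-step chain reduction therefore measures ≈5.5% RMS against its full
  chain at x10 = 100 — just above the 5% figure the Michaelis–Menten
  pathway meets.  The D-factor handles the mirror-image effect for
  *initial* imaginary molecules only.
* The rejection variant discards the residual waiting time at queue
  interruptions, slightly delaying firings in completion-dense phases.
* Heterogeneous per-step rates are supported in the chain simulators but
  not inside a single state-dependent channel (the closed form assumes a
  common k); chains with well-separated time scales should be split into
  multiple channels.
* Time-varying propensities are piecewise-constant between events, not
  integrated-hazard exact.
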