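"""State-dependent time delay for the reduced delayed reaction pair.

A chain X1 -> X2 -> ... -> Xn -> P with equal per-step rate k is reduced to

    consuming:     X1 --k x1--> G        (fires at the SSA event time)
    nonconsuming:  G  --delay--> P       (completes tau time units later)

where the imaginary species G counts molecules in transit through the lumped
intermediate states.  The delay is the time tau2 for the total count to fall
from x1 + y to x1 - 1, computed from the chain's closed-form solution.  With
z = k*tau2 the crossing condition reduces, via a Taylor remainder evaluated
at the midpoint xi = tau2/2, to the transcendental equation

    C1 * z^n * e^{-z/2} / n! = 1 + C2 * y

with C1 = x1 - y/(n-1) and C = (1 + C2*y) * n! / C1, i.e. z^n e^{-z/2} = C,
solved in closed form by the Lambert W function.  The coefficient C2
(exactly 1 - z/(n-1), which still contains tau2) is replaced by a fitted
state-only approximation; see :func:`coeff_C2`.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln, lambertw

__all__ = [
    "DelayState",
    "DelayCoefficients",
    "MMParams",
    "DelayDomainError",
    "coeff_C1",
    "alpha_of",
    "beta_of",
    "coeff_C2",
    "tau2_closed_form",
    "tau2_robust",
    "state_delay",
    "harmonic_means",
    "mm_effective_rate",
]

#: floor for a computed delay; a completion must be strictly after its firing
EPS_DELAY = 1e-9

# fitted hyper-coefficients of the C2 approximation: alpha = A0 + A1/x1 is the
# plateau height of C2 at moderate y, beta = B0 + B1*x1 locates the state
# where C2 crosses -1/y (the C1 = 0 locus; B1 is close to n-1 = 8 of the
# nine-step calibration chain)
ALPHA_COEFFS = (3.25, 7.5)
BETA_COEFFS = (11.8, 8.2)
CALIBRATION_STEPS = 9  # chain length the default coefficients were fitted at


class DelayDomainError(ValueError):
    """The closed-form delay equation has no physical root for this state."""


@dataclass(frozen=True)
class DelayState:
    """Current state of a reduced channel: counts (x1, y), rate k, steps n."""

    x1: int
    y: int
    k: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("a lumped chain needs n >= 2 steps")
        if self.x1 < 0 or self.y < 0:
            raise ValueError("counts must be non-negative")
        if not self.k > 0:
            raise ValueError("rate k must be positive")


@dataclass(frozen=True)
class DelayCoefficients:
    """Coefficients of the delay equation for one state."""

    C1: float
    C2: float
    C: float
    alpha: float
    beta: float


@dataclass(frozen=True)
class MMParams:
    """Michaelis-Menten parameters of a lumped multistep pathway.

    ``V`` and ``K`` are the maximal rates and equilibrium constants of the
    individual steps 2..n (molecules/time and molecules); ``Vbar``/``Kbar``
    are their harmonic means, used as the effective lumped parameters.
    """

    V: tuple[float, ...]
    K: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.V) != len(self.K) or len(self.V) < 1:
            raise ValueError("V and K must be equal-length, non-empty")
        if min(self.V) <= 0 or min(self.K) <= 0:
            raise ValueError("all V_i and K_i must be positive")

    @property
    def Vbar(self) -> float:
        return harmonic_means(self)[0]

    @property
    def Kbar(self) -> float:
        return harmonic_means(self)[1]

    @property
    def Kbar_weighted(self) -> float:
        """Rate-weighted effective K: Vbar * mean(K_i / V_i).

        With this K the lumped form Vbar*x/(Kbar_weighted + x) equals the
        harmonic mean of the per-step rates V_i*x/(K_i + x) exactly in the
        pseudo-first-order regime; the plain harmonic mean of the K_i only
        coincides when all steps share the same V."""
        V = np.asarray(self.V, dtype=float)
        K = np.asarray(self.K, dtype=float)
        return float(self.Vbar * np.mean(K / V))


def coeff_C1(x1: float, y: float, n: int) -> float:
    """C1 = x1 + y - n*y/(n-1) = x1 - y/(n-1)."""
    if n < 2:
        raise ValueError("n must be >= 2")
    return x1 + y - n * y / (n - 1)


def alpha_of(x1: float) -> float:
    """Plateau of the C2 approximation, alpha = 3.25 + 7.5/x1."""
    if x1 < 1:
        raise ValueError("x1 must be >= 1")
    a0, a1 = ALPHA_COEFFS
    return a0 + a1 / x1


def beta_of(x1: float) -> float:
    """Crossing scale of the C2 approximation, beta = 11.8 + 8.2*x1."""
    if x1 < 1:
        raise ValueError("x1 must be >= 1")
    b0, b1 = BETA_COEFFS
    return b0 + b1 * x1


def coeff_C2(x1: float, y: float, n: int = CALIBRATION_STEPS,
             alpha: float | None = None, beta: float | None = None) -> float:
    """Fitted state-only approximation of C2.

        C2(x1, y) = alpha * (1 + 1/y) * (1 - y/beta) - 1/y

    Strictly decreasing in y; equals -1/y exactly at y = beta.  Since the
    exact C2 forces 1 + C2*y = 0 on the locus C1 = 0 (y = (n-1)*x1), beta
    marks that locus; the default coefficients were fitted on a nine-step
    chain, so for other chain lengths beta is rescaled by (n-1)/8.
    """
    if y <= 0:
        raise ValueError("C2 is defined for y >= 1; the y = 0 delay branch "
                         "bypasses it")
    if alpha is None:
        alpha = alpha_of(x1)
    if beta is None:
        beta = beta_of(x1) * (n - 1) / (CALIBRATION_STEPS - 1)
    return alpha * (1.0 + 1.0 / y) * (1.0 - y / beta) - 1.0 / y


def _z_from_C(C: float, n: int) -> float:
    """Solve z^n * e^{-z/2} = C for the physical root 0 < z < 2n.

    Via w*e^w = -C^{1/n}/(2n) with w = -z/(2n): the first crossing of the
    total-count curve is the smaller of the two positive roots, i.e. the
    principal Lambert branch W0.
    """
    if not C > 0:
        raise DelayDomainError(f"delay equation needs C > 0, got C={C!r}")
    # C^(1/n) in log space; n! cancellation is done by the caller
    arg = -np.exp(np.log(C) / n) / (2 * n)
    if arg < -1.0 / np.e:
        raise DelayDomainError(
            f"Lambert W argument {arg:.6g} < -1/e (C={C:.6g}, n={n}); "
            "no real root")
    w = float(np.real(lambertw(arg, 0)))
    return -2 * n * w


def tau2_closed_form(state: DelayState, alpha: float | None = None,
                     beta: float | None = None,
                     self_consistent: bool = False) -> float:
    """Closed-form delay tau2 for the current state.

    Dispatches on the state:

    * ``y == 0``: C = n!/x1 and tau2 = -2n/k * W0(-C^{1/n}/(2n)),
    * ``C1 == 0``: the equation degenerates to 1 + C2*y = 0 with the exact
      C2 = 1 - k*tau2/(n-1), giving tau2 = (n-1)(1 + 1/y)/k,
    * otherwise: C = (1 + C2*y) * n!/C1 with the fitted C2, solved by W0.

    ``self_consistent=True`` replaces the fitted C2 by the exact
    tau2-dependent form and solves the fixed point numerically (validation
    mode; slower, no Lambert W closed form).

    Raises :class:`DelayDomainError` when the fitted C2 yields a C outside
    the real Lambert domain (use :func:`tau2_robust` inside simulations).
    """
    x1, y, k, n = state.x1, state.y, state.k, state.n
    if x1 < 1:
        raise ValueError("a consuming firing needs x1 >= 1")
    if self_consistent:
        return _tau2_self_consistent(state)
    log_nfact = float(gammaln(n + 1))
    if y == 0:
        C = np.exp(log_nfact - np.log(x1))
        return _z_from_C(C, n) / k
    C1 = coeff_C1(x1, y, n)
    if C1 == 0:
        return (n - 1) * (1.0 + 1.0 / y) / k
    C2 = coeff_C2(x1, y, n, alpha=alpha, beta=beta)
    C = (1.0 + C2 * y) * np.exp(log_nfact) / C1
    try:
        return _z_from_C(C, n) / k
    except DelayDomainError as err:
        raise DelayDomainError(
            f"state (x1={x1}, y={y}, k={k}, n={n}): {err}") from None


def _total_series(z: float, x1: float, y: float, n: int) -> float:
    """Exact expected total count of the chain at scaled time z = k*t."""
    j = np.arange(n)
    pois = np.exp(j * np.log(z) - gammaln(j + 1) - z) if z > 0 else \
        np.eye(1, n, 0).ravel()
    s = x1 * pois.sum()
    if y > 0:
        w = (n - 1 - j[: n - 1]) / (n - 1)
        s += y * (pois[: n - 1] * w).sum()
    return float(s)


def _tau2_exact_crossing(state: DelayState) -> float:
    """Root of the exact-series crossing s(tau2) = x1 - 1.

    For x1 = 1 the literal threshold is zero, which the mean total only
    reaches asymptotically; the crossing is floored at half a molecule (the
    usual discreteness convention for an emptying system).
    """
    x1, y, k, n = state.x1, state.y, state.k, state.n
    threshold = max(x1 - 1, 0.5)
    f = lambda z: _total_series(z, x1, y, n) - threshold
    hi = 2.0 * n
    while f(hi) > 0:
        hi *= 2.0
    return brentq(f, 1e-12, hi, xtol=1e-12, rtol=1e-12) / k

def _tau2_self_consistent(state: DelayState) -> float:
    """Solve the delay equation with the exact C2 = 1 - k*tau2/(n-1)."""
    x1, y, k, n = state.x1, state.y, state.k, state.n
    log_nfact = float(gammaln(n + 1))
    C1 = coeff_C1(x1, y, n)

    def f(z: float) -> float:
        lhs = C1 * np.exp(n * np.log(z) - z / 2 - log_nfact) if z > 0 else 0.0
        return lhs - (1.0 + (1.0 - z / (n - 1)) * y)

    hi = 2.0 * n
    while f(hi) < 0 and hi < 1e6:
        hi *= 2.0
    return brentq(f, 1e-12, hi, xtol=1e-12, rtol=1e-12) / k


def tau2_robust(state: DelayState, alpha: float | None = None,
                beta: float | None = None) -> float:
    """tau2 via the closed form, falling back to the exact-series crossing.

    The fitted C2 can push C outside the Lambert domain near the C1 = 0
    locus or deep in the overloaded regime y > (n-1)*x1; there the exact
    crossing of the chain's closed-form total (which always has a unique
    root) is used instead.
    """
    try:
        return tau2_closed_form(state, alpha=alpha, beta=beta)
    except DelayDomainError:
        return _tau2_exact_crossing(state)


def state_delay(state: DelayState, tau1: float,
                rng: np.random.Generator | None = None,
                stochastic: bool = False) -> float:
    """Time delay tau = max(tau2 - tau1, eps) for a consuming firing.

    ``tau1`` is the SSA waiting time of the firing.  With
    ``stochastic=True`` an Erlang(n-1) sample with mean tau2 replaces the
    deterministic tau2 (the n-1 lumped steps motivate the shape).
    """
    if tau1 < 0:
        raise ValueError("tau1 must be >= 0")
    tau2 = tau2_robust(state)
    if stochastic:
        if rng is None:
            raise ValueError("stochastic delays need an rng")
        shape = state.n - 1
        tau2 = rng.gamma(shape, tau2 / shape)
    return max(tau2 - tau1, EPS_DELAY)


def harmonic_means(params: MMParams) -> tuple[float, float]:
    """Harmonic means (Vbar, Kbar) of the per-step MM parameters."""
    V = np.asarray(params.V, dtype=float)
    K = np.asarray(params.K, dtype=float)
    m = len(V)
    return float(m / np.sum(1.0 / V)), float(m / np.sum(1.0 / K))


def mm_effective_rate(U: float, params: MMParams) -> float:
    """Effective per-molecule rate of the lumped Michaelis-Menten channel.

    The lumped steps see on average U/(n-1) molecules each; the effective
    first-order rate fed to the delay formula is the harmonic mean of the
    per-step per-molecule rates V_i/(K_i + U/(n-1)), equivalently

        k_eff = Vbar / (Kbar_weighted + U/(n-1))

    with Vbar the harmonic mean of the V_i and Kbar_weighted the
    rate-weighted effective K (see :class:`MMParams`).  The harmonic mean
    is what preserves the summed passage time through the steps, and hence
    the fidelity of the reduced model.
    """
    if U < 0:
        raise ValueError("U must be non-negative")
    m = len(params.V)
    return params.Vbar / (params.Kbar_weighted + U / m)
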