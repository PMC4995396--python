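"""Exact representations of a multistep reaction chain.

The chain is the sequence of first-order conversions

    X1 -> X2 -> ... -> Xn -> P,      rate k_i * x_i for step i,

with ``x10`` molecules initially in X1 and ``y0`` molecules spread over the
intermediate states X2..Xn.  Three equivalent descriptions are provided and
serve as ground truth for every delayed reduction built on top of them:

* :func:`analytic_total` -- closed-form expected total count (equal rates),
* :func:`ode_totals` -- numerical integration of the rate equations,
* :func:`ssa_chain` -- exact Gillespie simulation with a full event log.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.special import gammaln

from .trajectory import Trajectory, sample_piecewise

__all__ = [
    "ChainSpec",
    "ChainRealization",
    "initial_partition",
    "analytic_total",
    "ode_totals",
    "ssa_chain",
    "ensemble_total",
]


@dataclass(frozen=True)
class ChainSpec:
    """An n-step reaction chain with initial occupancy.

    Parameters
    ----------
    n:
        Number of sequential reaction steps (>= 1).
    k:
        Per-step rate constant (1/time), a scalar for equal rates or a
        length-``n`` vector of per-step rates.
    x10:
        Initial count in the first state X1.
    y0:
        Initial total count spread over the intermediate states X2..Xn.
    """

    n: int
    k: float | tuple[float, ...]
    x10: int
    y0: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.x10 < 0 or self.y0 < 0:
            raise ValueError("initial counts must be non-negative")
        if self.n == 1 and self.y0 > 0:
            raise ValueError("y0 > 0 requires intermediate states (n >= 2)")
        rates = self.rates
        if rates.shape != (self.n,):
            raise ValueError(f"k must be scalar or length-{self.n}")
        if not np.all(np.isfinite(rates)) or np.any(rates < 0):
            raise ValueError("rates must be finite and non-negative")

    @property
    def rates(self) -> np.ndarray:
        k = self.k
        if np.isscalar(k):
            return np.full(self.n, float(k))
        return np.asarray(k, dtype=float)

    @property
    def equal_rates(self) -> bool:
        r = self.rates
        return bool(np.all(r == r[0]))

    @property
    def initial_state(self) -> np.ndarray:
        """Initial occupancy of states X1..Xn (product excluded)."""
        if self.n == 1:
            return np.array([self.x10])
        return np.concatenate(([self.x10], initial_partition(self.y0, self.n)))

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(f"X{i}" for i in range(1, self.n + 1)) + ("P",)


def initial_partition(y0: int, n: int) -> np.ndarray:
    """Spread ``y0`` intermediate molecules over states X2..Xn.

    Counts are non-increasing along the chain, sum to ``y0`` and differ by at
    most one; e.g. ``y0=6, n=5`` gives ``(2, 2, 1, 1)``.
    """
    if y0 < 0:
        raise ValueError("y0 must be non-negative")
    if n < 2:
        if y0 > 0:
            raise ValueError("no intermediate states exist for n < 2")
        return np.zeros(0, dtype=int)
    base, extra = divmod(int(y0), n - 1)
    return np.array([base + (1 if i < extra else 0) for i in range(n - 1)], dtype=int)


def analytic_total(chain: ChainSpec, t: float | np.ndarray) -> float | np.ndarray:
    """Closed-form expected total count s(t) = E[x1 + ... + xn] at time t.

    Requires equal per-step rates.  The X1-seeded part is the Erlang(n)
    survival series; the intermediates contribute with the deterministic
    uniform partition y0/(n-1) per state:

        s(t) = e^{-kt} [ x10 * sum_{j=0}^{n-1} (kt)^j / j!
                         + y0 * sum_{j=0}^{n-2} (n-1-j)/(n-1) * (kt)^j / j! ]
    """
    if not chain.equal_rates:
        raise ValueError("analytic_total requires equal rates; use ode_totals")
    k = chain.rates[0]
    n = chain.n
    z = np.atleast_1d(np.asarray(t, dtype=float)) * k
    if np.any(z < 0):
        raise ValueError("t must be >= 0")
    j = np.arange(n)
    # terms computed in log space to stay finite for large n and kt
    log_pois = j[None, :] * np.log(np.where(z[:, None] > 0, z[:, None], 1.0)) \
        - gammaln(j[None, :] + 1) - z[:, None]
    pois = np.exp(log_pois)
    pois[z == 0] = 0.0
    pois[z == 0, 0] = 1.0
    s = chain.x10 * pois.sum(axis=1)
    if n >= 2 and chain.y0 > 0:
        w = (n - 1 - j[: n - 1]) / (n - 1)
        s = s + chain.y0 * (pois[:, : n - 1] * w).sum(axis=1)
    return s if np.ndim(t) else float(s[0])


def ode_totals(chain: ChainSpec, t_grid: np.ndarray, rtol: float = 1e-10,
               atol: float = 1e-12, full: bool = False):
    """Integrate the chain rate equations; return totals on ``t_grid``.

    Supports unequal rates.  ``full=True`` additionally returns the per-state
    solution including the product (shape ``(len(t_grid), n + 1)``).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or np.any(np.diff(t_grid) <= 0) or t_grid[0] < 0:
        raise ValueError("t_grid must be increasing and start at t >= 0")
    rates = chain.rates
    n = chain.n

    def rhs(_t, x):
        flux = rates * x[:n]
        dx = np.empty(n + 1)
        dx[0] = -flux[0]
        dx[1:n] = flux[: n - 1] - flux[1:n]
        dx[n] = flux[n - 1]
        return dx

    x0 = np.concatenate((chain.initial_state.astype(float), [0.0]))
    t0, t1 = t_grid[0], t_grid[-1]
    if t1 == t0:
        sol_y = np.tile(x0, (len(t_grid), 1))
    else:
        sol = solve_ivp(rhs, (t0, t1), x0, t_eval=t_grid, rtol=rtol, atol=atol,
                        method="LSODA")
        if not sol.success:
            raise RuntimeError(f"ODE integration failed: {sol.message}")
        sol_y = sol.y.T
    totals = sol_y[:, :n].sum(axis=1)
    if full:
        return totals, sol_y
    return totals


@dataclass
class ChainRealization:
    """One exact SSA realization of a chain with its full event log.

    ``reaction`` holds, per event, the 0-based step index that fired
    (step i converts X_{i+1-1}; step n-1 produces P).  The state trajectory
    can be reconstructed from the log; ``totals`` caches the running total
    count (product excluded) after each event.
    """

    chain: ChainSpec
    times: np.ndarray
    reaction: np.ndarray
    seed: int | None

    @property
    def totals(self) -> np.ndarray:
        drop = np.where(self.reaction == self.chain.n - 1, 1, 0)
        return self.chain.x10 + self.chain.y0 - np.cumsum(drop)

    def total_on_grid(self, grid: np.ndarray) -> np.ndarray:
        return sample_piecewise(self.times, self.totals.astype(float),
                                np.asarray(grid, float),
                                float(self.chain.x10 + self.chain.y0))

    def to_trajectory(self, grid: np.ndarray) -> Trajectory:
        grid = np.asarray(grid, dtype=float)
        n = self.chain.n
        counts = np.zeros((len(self.times), n + 1))
        x = np.concatenate((self.chain.initial_state.astype(float), [0.0]))
        for i, r in enumerate(self.reaction):
            x[r] -= 1
            x[r + 1] += 1
            counts[i] = x
        init = np.concatenate((self.chain.initial_state.astype(float), [0.0]))
        cols = [sample_piecewise(self.times, counts[:, s], grid, init[s])
                for s in range(n + 1)]
        return Trajectory(grid, np.column_stack(cols), self.chain.species,
                          replicate=0, seed=self.seed)


def ssa_chain(chain: ChainSpec, t_end: float = np.inf,
              seed: int | np.random.Generator | None = None) -> ChainRealization:
    """Exact Gillespie simulation of the chain with mass-action propensities.

    Runs until ``t_end`` or until the chain empties, recording every firing
    (reaction index and time).  Reproducible under a fixed seed.
    """
    if not (t_end > 0):
        raise ValueError("t_end must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rates = chain.rates
    x = chain.initial_state.astype(np.int64).copy()
    t = 0.0
    times: list[float] = []
    which: list[int] = []
    n = chain.n
    while True:
        a = rates * x
        a0 = a.sum()
        if a0 <= 0.0:
            break
        t += rng.exponential(1.0 / a0)
        if t > t_end:
            break
        j = int(np.searchsorted(np.cumsum(a), rng.random() * a0))
        j = min(j, n - 1)
        x[j] -= 1
        if j < n - 1:
            x[j + 1] += 1
        times.append(t)
        which.append(j)
    return ChainRealization(chain, np.array(times), np.array(which, dtype=int),
                            seed if isinstance(seed, int) else None)


def ensemble_total(chain: ChainSpec, grid: np.ndarray, reps: int,
                   seed: int | None = None, t_end: float | None = None):
    """Ensemble mean and standard error of the total count on ``grid``."""
    grid = np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    acc = np.zeros(len(grid))
    acc2 = np.zeros(len(grid))
    horizon = t_end if t_end is not None else grid[-1] * 1.0000001
    for _ in range(reps):
        real = ssa_chain(chain, t_end=horizon, seed=rng)
        tot = real.total_on_grid(grid)
        acc += tot
        acc2 += tot * tot
    mean = acc / reps
    var = np.maximum(acc2 / reps - mean**2, 0.0)
    se = np.sqrt(var / reps)
    return mean, se
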