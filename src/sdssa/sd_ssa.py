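"""Rejection delay-SSA with elementary, constant-, distributed- and
state-dependent-delay channels (the SD-SSA engine).

Each delayed reaction is split into a consuming part, applied when the
channel fires, and a manifesting (nonconsuming) part applied when the
scheduled completion time is reached.  Scheduled completions live in a
min-ordered queue; whenever the earliest completion falls inside the drawn
waiting interval the engine advances to it, applies the manifesting update
and discards the drawn waiting time (rejection semantics -- propensities
are recomputed on the next step).
"""
from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .delay_formula import (DelayState, EPS_DELAY, MMParams,
                            mm_effective_rate, state_delay, tau2_robust)
from .trajectory import Trajectory, sample_piecewise

__all__ = [
    "Channel",
    "DelayQueue",
    "System",
    "SystemState",
    "propensities",
    "draw_waiting",
    "step",
    "run",
    "ensemble_mean",
    "schedule_initial_imaginary",
    "mass_action",
    "michaelis_menten",
    "time_varying",
    "constant_delay",
    "distributed_delay",
    "state_dependent_delay",
]


# ---------------------------------------------------------------------------
# propensity and delay policy descriptors

def mass_action(rate: float, species: str):
    """First-order mass-action propensity a = rate * x[species].

    ``species=None`` gives a zero-order (birth) channel with a = rate."""
    return ("mass_action", float(rate), species)


def michaelis_menten(V: float, K: float, species: str):
    """Saturating propensity a = V * x / (K + x)."""
    return ("mm", float(V), float(K), species)


def time_varying(fn: Callable[[float], float]):
    """Propensity given by an explicit function of time, a = fn(t).

    Treated as constant between events (adequate when the profile changes
    slowly relative to the event rate)."""
    return ("timevar", fn)


def constant_delay(tau: float):
    return ("constant", float(tau))


def distributed_delay(sampler: Callable[[np.random.Generator], float]):
    return ("distributed", sampler)


def state_dependent_delay(x1_species: str, k: float | None = None,
                          n: int = 9, mm: MMParams | None = None,
                          stochastic: bool = False):
    """Delay computed from the current state via the lumped-chain formula.

    ``x1_species`` names the consumed species whose count enters as x1; the
    imaginary species of the channel supplies y.  Either a first-order rate
    ``k`` or Michaelis-Menten parameters ``mm`` (whose effective rate is
    re-evaluated at the current y) must be given.
    """
    if (k is None) == (mm is None):
        raise ValueError("give exactly one of k or mm")
    return ("state_dependent", x1_species, k, int(n), mm, bool(stochastic))


@dataclass
class Channel:
    """A reaction channel with consuming and manifesting stoichiometry.

    ``nu`` is applied at firing, ``u`` at the scheduled completion (empty
    for non-delayed channels).  A delayed channel must name exactly one
    imaginary species that ``nu`` increments and ``u`` decrements; its count
    always equals the number of queued completions for the channel.
    """

    name: str
    propensity: tuple
    nu: dict[str, int]
    u: dict[str, int] = field(default_factory=dict)
    delay: tuple | None = None
    imaginary: str | None = None

    def __post_init__(self) -> None:
        if self.delay is not None:
            if self.imaginary is None:
                raise ValueError(f"delayed channel {self.name!r} needs an "
                                 "imaginary species")
            if self.nu.get(self.imaginary, 0) != 1 or \
                    self.u.get(self.imaginary, 0) != -1:
                raise ValueError(
                    f"channel {self.name!r}: nu must add and u must remove "
                    "one molecule of the imaginary species")
        elif self.u:
            raise ValueError(f"non-delayed channel {self.name!r} must have "
                             "an empty manifesting update")


class DelayQueue:
    """Min-ordered collection of scheduled completion events."""

    def __init__(self) -> None:
        self._heap: list[tuple[float, int, int]] = []
        self._count = 0

    def push(self, completion_time: float, channel_index: int) -> None:
        heapq.heappush(self._heap, (completion_time, self._count, channel_index))
        self._count += 1

    def peek(self) -> tuple[float, int]:
        d, _, j = self._heap[0]
        return d, j

    def pop(self) -> tuple[float, int]:
        d, _, j = heapq.heappop(self._heap)
        return d, j

    @property
    def delta_min(self) -> float:
        return self._heap[0][0] if self._heap else math.inf

    def __len__(self) -> int:
        return len(self._heap)

    def per_channel(self, m: int) -> np.ndarray:
        out = np.zeros(m, dtype=int)
        for _, _, j in self._heap:
            out[j] += 1
        return out


@dataclass
class SystemState:
    """Species counts and current time of a running simulation."""

    counts: np.ndarray
    t: float = 0.0


@dataclass
class System:
    """A set of species and channels ready to simulate.

    ``preload`` optionally schedules initial imaginary-species completions:
    a list of ``(channel_name, count, window)`` tuples enqueuing ``count``
    completions uniformly on ``[0, window]`` at the start of every run.
    """

    species: tuple[str, ...]
    initial: dict[str, int]
    channels: list[Channel]
    preload: list[tuple[str, int, float]] = field(default_factory=list)
    time_unit: str = "arbitrary"

    def __post_init__(self) -> None:
        self.index = {s: i for i, s in enumerate(self.species)}
        for ch in self.channels:
            for s in list(ch.nu) + list(ch.u):
                if s not in self.index:
                    raise ValueError(f"channel {ch.name!r} references unknown "
                                     f"species {s!r}")
        for s in self.initial:
            if s not in self.index:
                raise ValueError(f"unknown species {s!r} in initial counts")
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            raise ValueError("channel names must be unique")

    def initial_counts(self) -> np.ndarray:
        x = np.zeros(len(self.species), dtype=np.int64)
        for s, c in self.initial.items():
            if c < 0:
                raise ValueError("initial counts must be non-negative")
            x[self.index[s]] = c
        return x

    def validate(self, state: SystemState, queue: DelayQueue) -> None:
        """Check the queue/imaginary-species pairing invariant."""
        per = queue.per_channel(len(self.channels))
        for j, ch in enumerate(self.channels):
            if ch.imaginary is not None:
                have = state.counts[self.index[ch.imaginary]]
                if have != per[j]:
                    raise RuntimeError(
                        f"imaginary species {ch.imaginary!r} count {have} != "
                        f"{per[j]} queued completions")


def propensities(state: SystemState, channels: Sequence[Channel],
                 system: System, t: float | None = None):
    """Propensity vector a_j and total a0 at the current state and time."""
    if t is None:
        t = state.t
    a = np.zeros(len(channels))
    x = state.counts
    for j, ch in enumerate(channels):
        p = ch.propensity
        kind = p[0]
        if kind == "mass_action":
            _, rate, sp = p
            a[j] = rate if sp is None else rate * x[system.index[sp]]
        elif kind == "mm":
            _, V, K, sp = p
            xv = x[system.index[sp]]
            a[j] = V * xv / (K + xv) if xv > 0 else 0.0
        elif kind == "timevar":
            a[j] = max(float(p[1](t)), 0.0)
        else:  # pragma: no cover - descriptor constructors prevent this
            raise ValueError(f"unknown propensity kind {kind!r}")
    if np.any(a < 0):
        raise ValueError("negative propensity")
    return a, float(a.sum())


def draw_waiting(a0: float, rng: np.random.Generator) -> float:
    """Exponential waiting time mu = -ln(r1)/a0; +inf when a0 = 0."""
    if a0 < 0:
        raise ValueError("a0 must be >= 0")
    if a0 == 0.0:
        return math.inf
    return -math.log(rng.random()) / a0


def _compute_delay(system: System, ch: Channel, state: SystemState,
                   mu: float, rng: np.random.Generator,
                   cache: dict | None = None) -> float:
    kind = ch.delay[0]
    if kind == "constant":
        return ch.delay[1]
    if kind == "distributed":
        return max(float(ch.delay[1](rng)), EPS_DELAY)
    # state-dependent: evaluated from the state immediately BEFORE applying
    # nu, so x1 still counts the firing molecule and y the pre-firing queue
    _, x1_sp, k, n, mm, stochastic = ch.delay
    x1 = int(state.counts[system.index[x1_sp]])
    y = int(state.counts[system.index[ch.imaginary]])
    if mm is not None:
        k = mm_effective_rate(y, mm)
    if stochastic:
        return state_delay(DelayState(x1, y, k, n), mu, rng, stochastic=True)
    if cache is not None:
        key = (id(ch), x1, y)
        tau2 = cache.get(key)
        if tau2 is None:
            tau2 = tau2_robust(DelayState(x1, y, k, n))
            cache[key] = tau2
        return max(tau2 - mu, EPS_DELAY)
    return state_delay(DelayState(x1, y, k, n), mu)


def step(state: SystemState, queue: DelayQueue, system: System,
         rng: np.random.Generator, _cache: dict | None = None,
         max_step: float = math.inf) -> bool:
    """Advance the simulation by one event; returns False when exhausted.

    Rejection semantics: if the earliest queued completion precedes t + mu,
    time advances to it, the manifesting update is applied and mu is
    discarded.  Otherwise the firing channel j is drawn categorically, its
    consuming update applied, and -- if delayed -- a completion is pushed at
    t + mu + tau.  A queued completion wins ties.

    ``max_step`` bounds the jump for systems with time-varying rates: a
    drawn waiting time beyond it advances time without firing, so rates are
    re-evaluated at that resolution (piecewise-constant approximation).
    """
    a, a0 = propensities(state, system.channels, system)
    mu = draw_waiting(a0, rng)
    t_next = state.t + mu
    cap = state.t + max_step
    if len(queue) and queue.delta_min <= min(t_next, cap):
        d, jq = queue.pop()
        state.t = d
        _apply(state, system, system.channels[jq].u)
        return True
    if t_next > cap:
        # no firing inside the resolution window; rate gets re-evaluated
        state.t = cap
        return True
    if not math.isfinite(t_next):
        return False
    state.t = t_next
    j = int(np.searchsorted(np.cumsum(a), rng.random() * a0))
    j = min(j, len(system.channels) - 1)
    ch = system.channels[j]
    if ch.delay is not None:
        tau = _compute_delay(system, ch, state, mu, rng, _cache)
        queue.push(state.t + tau, j)
    _apply(state, system, ch.nu)
    return True


def _apply(state: SystemState, system: System, update: dict[str, int]) -> None:
    for s, d in update.items():
        i = system.index[s]
        state.counts[i] += d
        if state.counts[i] < 0:
            raise RuntimeError(f"negative count for species {s!r}; "
                               "bad stoichiometry")


def schedule_initial_imaginary(y0: int, MT: float, channel_index: int,
                               rng: np.random.Generator,
                               queue: DelayQueue) -> np.ndarray:
    """Enqueue ``y0`` completions at i.i.d. uniform times on [0, MT].

    Models imaginary molecules already partway through the lumped chain at
    t = 0, whose remaining manifestation times are spread over a window MT
    shorter than the full initial delay.
    """
    if y0 < 0:
        raise ValueError("y0 must be >= 0")
    if y0 > 0 and not MT > 0:
        raise ValueError("MT must be > 0")
    times = rng.uniform(0.0, MT, size=int(y0))
    for d in times:
        queue.push(float(d), channel_index)
    return times


def run(system: System, t_end: float, seed: int | np.random.Generator | None = None,
        record_grid: np.ndarray | None = None,
        drain_queue: bool = True, probe_dt: float | None = None) -> Trajectory:
    """Simulate until ``t_end``; deterministic under a fixed seed.

    With ``drain_queue`` (default) completions already scheduled before
    ``t_end`` are resolved even after propensities vanish.  Counts are
    recorded on ``record_grid`` when given, else at every event.  When all
    propensities vanish but a time-varying channel could reactivate, time
    is advanced in hops of ``probe_dt`` (default t_end/2000).
    """
    if not t_end >= 0:
        raise ValueError("t_end must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    state = SystemState(system.initial_counts(), 0.0)
    queue = DelayQueue()
    chan_index = {c.name: j for j, c in enumerate(system.channels)}
    for name, count, window in system.preload:
        j = chan_index[name]
        ch = system.channels[j]
        schedule_initial_imaginary(count, window, j, rng, queue)
        state.counts[system.index[ch.imaginary]] += count
    times = [0.0]
    snaps = [state.counts.copy()]
    # deterministic tau2 values are reused across replicates of one system
    cache = getattr(system, "_tau2_cache", None)
    if cache is None:
        cache = system._tau2_cache = {}
    has_timevar = any(ch.propensity[0] == "timevar" for ch in system.channels)
    probe = probe_dt if probe_dt is not None else t_end / 2000.0
    while state.t < t_end:
        a, a0 = propensities(state, system.channels, system)
        if a0 == 0.0 and (not len(queue) or
                          (not drain_queue) or queue.delta_min > t_end):
            if has_timevar and probe > 0:
                # a time-varying rate may switch back on later
                state.t = min(state.t + probe, t_end)
                continue
            break
        max_step = probe if has_timevar else math.inf
        if not step(state, queue, system, rng, cache, max_step=max_step):
            break
        if state.t > t_end:
            # the event beyond the horizon is left unrecorded
            break
        times.append(state.t)
        snaps.append(state.counts.copy())
    counts = np.asarray(snaps, dtype=float)
    tarr = np.asarray(times)
    if record_grid is not None:
        grid = np.asarray(record_grid, dtype=float)
        cols = [sample_piecewise(tarr[1:], counts[1:, i], grid, counts[0, i])
                for i in range(counts.shape[1])]
        return Trajectory(grid, np.column_stack(cols), system.species,
                          seed=seed if isinstance(seed, int) else None)
    return Trajectory(tarr, counts, system.species,
                      seed=seed if isinstance(seed, int) else None)


def ensemble_mean(system: System, t_end: float, grid: np.ndarray, reps: int,
                  seed: int | None = None,
                  species: tuple[str, ...] | None = None) -> Trajectory:
    """Ensemble mean (with standard errors) of counts on ``grid``.

    ``species`` restricts the recorded columns; replicates use independent
    streams spawned from ``seed``.
    """
    grid = np.asarray(grid, dtype=float)
    names = species if species is not None else system.species
    idx = [system.species.index(s) for s in names]
    rng = np.random.default_rng(seed)
    acc = np.zeros((len(grid), len(idx)))
    acc2 = np.zeros_like(acc)
    for _ in range(reps):
        traj = run(system, t_end, rng, record_grid=grid)
        vals = traj.counts[:, idx]
        acc += vals
        acc2 += vals * vals
    mean = acc / reps
    var = np.maximum(acc2 / reps - mean**2, 0.0)
    se = np.sqrt(var / reps)
    return Trajectory(grid, mean, tuple(names), replicate="mean", seed=seed,
                      se=se)
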