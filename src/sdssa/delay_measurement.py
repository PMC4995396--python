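"""Empirical measurement of time delays from exact chain simulations.

For the j-th consuming firing X1 -> X2 (at time tau1, with x1 molecules in
X1 immediately before it and y intermediates) the delay ends at tau2, the
first time the total count -- X1 through Xn, product excluded -- drops to
x1 - 1.  The criterion is threshold-based, not particle-tracking: whichever
molecule completes the chain first ends the interval.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chain_core import ChainRealization, ChainSpec, ssa_chain

__all__ = ["DelayRecord", "measure_delays", "delays_frame", "average_delays"]

#: replicate count used for averaged delay curves
DEFAULT_REPLICATES = 1000


@dataclass(frozen=True)
class DelayRecord:
    """Delay bookkeeping for one consuming firing."""

    molecule_index: int  # 1-based order of the X1 -> X2 firing
    tau1: float          # firing time
    tau2: float          # first time the total equals x1_at_firing - 1
    x1_at_firing: int
    y_at_firing: int

    @property
    def delay(self) -> float:
        return self.tau2 - self.tau1


def measure_delays(chain: ChainSpec,
                   seed: int | np.random.Generator | None = None,
                   realization: ChainRealization | None = None) -> list[DelayRecord]:
    """One delay record per X1 -> X2 firing of a run-to-exhaustion SSA.

    The j-th firing leaves x1 = x10 - j molecules in X1, so its threshold
    total is x10 - j; because the total decreases by single steps it visits
    every level and each record closes at the exact threshold hit.
    """
    if chain.x10 < 1:
        raise ValueError("measuring delays needs x10 >= 1")
    real = realization if realization is not None else ssa_chain(chain, seed=seed)
    n = chain.n
    totals = real.totals
    # time at which the total first reaches each level (levels are hit in
    # descending order, one per product-forming event)
    drops = real.reaction == n - 1
    level_time = dict(zip(totals[drops], real.times[drops]))
    records: list[DelayRecord] = []
    x1 = chain.x10
    y = chain.y0
    j = 0
    for t, r, tot in zip(real.times, real.reaction, totals):
        if r == 0:
            j += 1
            records.append(DelayRecord(
                molecule_index=j, tau1=t, tau2=level_time[x1 - 1],
                x1_at_firing=x1, y_at_firing=y))
            x1 -= 1
            y += 1
        elif r == n - 1:
            y -= 1
    return records


def delays_frame(records: list[DelayRecord], replicate: int = 0,
                 seed: int | None = None) -> pd.DataFrame:
    """Tidy table of delay records."""
    return pd.DataFrame(
        {
            "replicate": replicate,
            "molecule_index": [r.molecule_index for r in records],
            "tau1": [r.tau1 for r in records],
            "tau2": [r.tau2 for r in records],
            "delay": [r.delay for r in records],
            "x1_at_firing": [r.x1_at_firing for r in records],
            "y_at_firing": [r.y_at_firing for r in records],
            "seed": seed,
        }
    )


def average_delays(chain: ChainSpec, reps: int = DEFAULT_REPLICATES,
                   seed: int | None = None) -> pd.DataFrame:
    """Per-molecule-index mean delay with standard error over ``reps`` runs.

    Columns: molecule_index, mean_delay, se_delay, mean_tau2, n_reps.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    x10 = chain.x10
    acc = np.zeros(x10)
    acc2 = np.zeros(x10)
    acc_t2 = np.zeros(x10)
    for _ in range(reps):
        recs = measure_delays(chain, seed=rng)
        d = np.array([r.delay for r in recs])
        acc += d
        acc2 += d * d
        acc_t2 += np.array([r.tau2 for r in recs])
    mean = acc / reps
    var = np.maximum(acc2 / reps - mean**2, 0.0)
    se = np.sqrt(var / reps) if reps > 1 else np.full(x10, np.nan)
    return pd.DataFrame(
        {
            "molecule_index": np.arange(1, x10 + 1),
            "mean_delay": mean,
            "se_delay": se,
            "mean_tau2": acc_t2 / reps,
            "n_reps": reps,
        }
    )
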