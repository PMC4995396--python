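"""Recorded trajectories of stochastic or deterministic simulations."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class Trajectory:
    """Time course of species counts for one realization or an ensemble mean.

    ``counts`` has shape ``(len(times), len(species))``.  ``replicate`` is an
    integer replicate index or the string ``"mean"`` for ensemble averages.
    """

    times: np.ndarray
    counts: np.ndarray
    species: tuple[str, ...]
    replicate: int | str = 0
    seed: int | None = None
    se: np.ndarray | None = None  # standard errors, ensemble means only

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.atleast_2d(np.asarray(self.counts, dtype=float))
        if self.counts.shape[0] != self.times.shape[0]:
            raise ValueError("counts and times have incompatible shapes")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("times must be non-decreasing")

    def total(self, species: tuple[str, ...] | None = None) -> np.ndarray:
        """Summed counts over ``species`` (default: all) at each time."""
        if species is None:
            return self.counts.sum(axis=1)
        idx = [self.species.index(s) for s in species]
        return self.counts[:, idx].sum(axis=1)

    def column(self, name: str) -> np.ndarray:
        return self.counts[:, self.species.index(name)]

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table: time, species, count, replicate, seed."""
        n_t, n_s = self.counts.shape
        frame = pd.DataFrame(
            {
                "time": np.repeat(self.times, n_s),
                "species": list(self.species) * n_t,
                "count": self.counts.ravel(),
                "replicate": self.replicate,
                "seed": self.seed,
            }
        )
        if self.se is not None:
            frame["se"] = self.se.ravel()
        return frame


def sample_piecewise(event_times: np.ndarray, values: np.ndarray,
                     grid: np.ndarray, initial: float) -> np.ndarray:
    """Sample a piecewise-constant, right-continuous path on ``grid``.

    ``values[i]`` is the value from ``event_times[i]`` (inclusive) onward;
    before the first event the path equals ``initial``.
    """
    idx = np.searchsorted(event_times, grid, side="right")
    out = np.empty(len(grid), dtype=float)
    out[idx == 0] = initial
    nz = idx > 0
    out[nz] = values[idx[nz] - 1]
    return out
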