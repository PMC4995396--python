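"""Re-derivation of the C2 approximation from measured delays.

Pipeline: measure delays on a grid of initial states (x1, y), invert the
closed-form delay equation per state for the C2 matching the measured
delay, fit the two-parameter C2(y; alpha, beta) family per x1, then fit
the hyper-laws alpha(x1) = a0 + a1/x1 and beta(x1) = b0 + b1*x1.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares

from .chain_core import ChainSpec
from .delay_formula import coeff_C1
from .delay_measurement import average_delays

__all__ = ["CalibrationResult", "optimal_C2", "fit_alpha_beta",
           "measure_c2_grid", "xi_diagnostic"]

# grid mirroring the scales of the delay-measurement figures
DEFAULT_X1_LEVELS = (5, 10, 20, 40)
DEFAULT_N = 9
DEFAULT_K = 0.126


@dataclass
class CalibrationResult:
    """Optimal C2 grid with per-x1 and hyper-level fits."""

    grid: pd.DataFrame                  # columns x1, y, c2_opt[, c2_fitted]
    n: int = DEFAULT_N
    k: float = DEFAULT_K
    per_x1: pd.DataFrame | None = None  # columns x1, alpha, beta, resid
    alpha_coeffs: tuple[float, float] | None = None  # (a0, a1)
    beta_coeffs: tuple[float, float] | None = None   # (b0, b1)
    residuals: np.ndarray | None = None


def optimal_C2(x1: int, y: int, k: float, n: int, measured_delay: float,
               bracket: tuple[float, float] = (-10.0, 10.0),
               tol: float = 1e-10) -> float:
    """C2 for which the closed-form tau2 equals ``measured_delay``.

    ``measured_delay`` is on the tau2 scale (firing-to-threshold time).
    Solved by bracketed root-finding on the delay residual; raises if no
    root exists inside ``bracket`` intersected with the feasibility domain
    of the Lambert solution.
    """
    if measured_delay <= 0:
        raise ValueError("measured_delay must be > 0")
    if y < 1:
        raise ValueError("optimal C2 needs y >= 1 (the y = 0 branch has "
                         "no C2)")
    C1 = coeff_C1(x1, y, n)
    if C1 == 0:
        # degenerate locus: tau2 is C2-independent; return the exact value
        return -1.0 / y

    def resid(c2: float) -> float:
        return _tau2_with_c2(x1, y, k, n, c2) - measured_delay

    # feasibility: C = (1 + c2*y) n!/C1 must lie in (0, (2n/e)^n)
    lo, hi = bracket
    if C1 > 0:
        lo = max(lo, (-1.0 + 1e-12) / y)
    else:
        hi = min(hi, (-1.0 - 1e-12) / y)
    lo_feas, hi_feas = _shrink_to_feasible(x1, y, k, n, lo, hi)
    f_lo, f_hi = resid(lo_feas), resid(hi_feas)
    if f_lo * f_hi > 0:
        raise ValueError(
            f"no bracketing root for (x1={x1}, y={y}, k={k}, n={n}, "
            f"delay={measured_delay}): resid({lo_feas:.4g})={f_lo:.4g}, "
            f"resid({hi_feas:.4g})={f_hi:.4g}")
    return brentq(resid, lo_feas, hi_feas, xtol=tol, rtol=4 * np.finfo(float).eps)


def _tau2_with_c2(x1: int, y: int, k: float, n: int, c2: float) -> float:
    """Closed-form tau2 with an explicitly supplied C2 value."""
    from .delay_formula import _z_from_C
    from scipy.special import gammaln
    C1 = coeff_C1(x1, y, n)
    C = (1.0 + c2 * y) * np.exp(float(gammaln(n + 1))) / C1
    return _z_from_C(C, n) / k


def _shrink_to_feasible(x1, y, k, n, lo, hi, steps=60):
    """Pull the bracket endpoints inside the Lambert feasibility domain."""
    def ok(c2):
        try:
            _tau2_with_c2(x1, y, k, n, c2)
            return True
        except Exception:
            return False
    if not ok(lo):
        lo2 = next((lo + (hi - lo) * i / steps for i in range(1, steps)
                    if ok(lo + (hi - lo) * i / steps)), None)
        if lo2 is None:
            raise ValueError("no feasible C2 in bracket")
        lo = lo2
    if not ok(hi):
        hi2 = next((hi - (hi - lo) * i / steps for i in range(1, steps)
                    if ok(hi - (hi - lo) * i / steps)), None)
        if hi2 is None:
            raise ValueError("no feasible C2 in bracket")
        hi = hi2
    return lo, hi


def measure_c2_grid(x1_levels=DEFAULT_X1_LEVELS, y_max_factor: int = 2,
                    n: int = DEFAULT_N, k: float = DEFAULT_K,
                    reps: int = 1000, seed: int | None = None) -> CalibrationResult:
    """Measure delays by simulation and invert for optimal C2 on a grid.

    For each x1 level, initial states (x10=x1, y0=y) for y in 1..y_max_factor*x1
    are simulated ``reps`` times; the mean tau2 of the first molecule is
    matched.  Mirrors the empirical calibration pipeline.
    """
    rows = []
    rng = np.random.default_rng(seed)
    for x1 in x1_levels:
        ys = _y_levels(x1, y_max_factor)
        for y in ys:
            chain = ChainSpec(n=n, k=k, x10=int(x1), y0=int(y))
            table = average_delays(chain, reps=reps,
                                   seed=int(rng.integers(2**31 - 1)))
            mean_tau2 = float(table["mean_tau2"].iloc[0])
            try:
                c2 = optimal_C2(int(x1), int(y), k, n, mean_tau2)
            except ValueError:
                c2 = np.nan
            rows.append((x1, y, mean_tau2, c2))
    grid = pd.DataFrame(rows, columns=["x1", "y", "mean_tau2", "c2_opt"])
    return CalibrationResult(grid=grid, n=n, k=k)


def _y_levels(x1: int, y_max_factor: int) -> np.ndarray:
    ymax = max(2, y_max_factor * x1)
    return np.unique(np.round(np.geomspace(1, ymax, min(ymax, 12))).astype(int))


def _c2_family(y: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    return alpha * (1.0 + 1.0 / y) * (1.0 - y / beta) - 1.0 / y


def fit_alpha_beta(calib: CalibrationResult) -> CalibrationResult:
    """Fit C2(y; alpha, beta) per x1, then the alpha/beta hyper-laws.

    Ordinary (unweighted) least squares on the C2 values themselves.
    Requires at least three x1 levels with three y levels each.  Returns
    the result with ``per_x1``, ``alpha_coeffs`` (a0, a1 of a0 + a1/x1) and
    ``beta_coeffs`` (b0, b1 of b0 + b1*x1) filled in.
    """
    grid = calib.grid.dropna(subset=["c2_opt"])
    x1_levels = sorted(grid["x1"].unique())
    if len(x1_levels) < 3:
        raise ValueError("need at least 3 x1 levels to fit the hyper-laws")
    rows = []
    for x1 in x1_levels:
        sub = grid[grid["x1"] == x1]
        if len(sub) < 3:
            raise ValueError(f"x1={x1}: need at least 3 y levels")
        yv = sub["y"].to_numpy(dtype=float)
        c2 = sub["c2_opt"].to_numpy(dtype=float)
        p0 = (max(c2.mean(), 0.5), 8.2 * float(x1) + 11.8)
        sol = least_squares(
            lambda p: _c2_family(yv, p[0], p[1]) - c2, p0,
            bounds=([1e-6, yv.max() * (1 + 1e-9)], [np.inf, np.inf]),
            xtol=1e-15, ftol=1e-15, gtol=1e-15)
        resid = float(np.sqrt(np.mean(sol.fun**2)))
        rows.append((x1, sol.x[0], sol.x[1], resid))
    per = pd.DataFrame(rows, columns=["x1", "alpha", "beta", "resid"])
    X = per["x1"].to_numpy(dtype=float)
    a1, a0 = np.polyfit(1.0 / X, per["alpha"].to_numpy(), 1)
    b1, b0 = np.polyfit(X, per["beta"].to_numpy(), 1)
    fitted = _c2_family(
        grid["y"].to_numpy(dtype=float),
        a0 + a1 / grid["x1"].to_numpy(dtype=float),
        b0 + b1 * grid["x1"].to_numpy(dtype=float))
    calib.per_x1 = per
    calib.alpha_coeffs = (float(a0), float(a1))
    calib.beta_coeffs = (float(b0), float(b1))
    calib.residuals = fitted - grid["c2_opt"].to_numpy(dtype=float)
    return calib


def xi_diagnostic(x1: int = 20, n: int = DEFAULT_N, k: float = DEFAULT_K,
                  fractions=(0.0, 0.25, 0.5, 0.75, 1.0),
                  reps: int = 1000, seed: int | None = None) -> pd.DataFrame:
    """Compare delay accuracy for remainder evaluation points xi = f*tau2.

    For y = 0 the delay equation with xi = f*tau2 is
    z^n e^{(f-1) z} = n!/x1, solved numerically per fraction f and compared
    with the measured mean tau2 of the first molecule.
    """
    from scipy.special import gammaln
    chain = ChainSpec(n=n, k=k, x10=x1, y0=0)
    measured = float(average_delays(chain, reps=reps, seed=seed)
                     ["mean_tau2"].iloc[0])
    log_target = float(gammaln(n + 1)) - np.log(x1)
    rows = []
    for f in fractions:
        g = lambda z: n * np.log(z) + (f - 1.0) * z - log_target
        if f < 1.0:
            hi = n / (1.0 - f)  # maximum of g; first root lies below it
            if g(hi) < 0:
                raise ValueError(f"no root for xi fraction {f}")
        else:
            hi = 2.0 * n
            while g(hi) < 0:
                hi *= 2
        z = brentq(g, 1e-9, hi)
        rows.append((f, z / k, measured, abs(z / k - measured) / measured))
    return pd.DataFrame(rows, columns=["xi_fraction", "tau2_formula",
                                       "tau2_measured", "rel_error"])
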