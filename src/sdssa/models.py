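"""Ready-to-run case-study systems and their full-chain ground-truth twins.

Three applications of the state-dependent-delay reduction:

* ``rpl30`` -- decay of RPL30 mRNA via an eight-step poly(A)-shortening
  chain plus terminal deadenylation (n = 9), reduced to one consuming and
  one nonconsuming reaction;
* ``swi5`` -- cell-cycle regulated SWI5 expression: delayed transcription
  driven by the NDD1 transcription factor, delayed nuclear export, and
  multistep cytosolic decay reduced to a state-dependent delay;
* ``glucosinolate`` -- a six-step Michaelis-Menten chain-elongation pathway
  of aliphatic glucosinolate biosynthesis, reduced with an effective
  harmonic-mean Michaelis-Menten rate.
"""
from __future__ import annotations

import math

from .chain_core import ChainSpec
from .delay_formula import DelayState, MMParams, tau2_robust
from .sd_ssa import (Channel, System, constant_delay, mass_action,
                     michaelis_menten, state_dependent_delay, time_varying)

__all__ = [
    "RPL30_DEFAULTS",
    "SWI5_DEFAULTS",
    "GLUCOSINOLATE_V",
    "GLUCOSINOLATE_K",
    "build_rpl30",
    "rpl30_chain_twin",
    "build_swi5",
    "ndd1_pulse",
    "build_glucosinolate",
]

# estimated parameters for the ACT1-UAS construct
RPL30_DEFAULTS = dict(s0=100, y0=23, k=0.1260, D=1.7184, n=9)

# estimated SWI5 parameters: regulation a, b; transcription and
# translocation delays (min); translocation and degradation rates (1/min)
SWI5_DEFAULTS = dict(a=9.148, b=3.390, tau_tx=46.665, tau_loc=0.733,
                     k2=2906.04, k3=1.297)

# maximal rates (molecules/time) and equilibrium constants (molecules) of
# the six elongation steps, converted from concentrations at a 4e-14 L cell
GLUCOSINOLATE_V = (37.07, 38.27, 73.44, 35.84, 9.31, 2.08)
GLUCOSINOLATE_K = (23859200.0, 12185600.0, 11852800.0, 9164800.0,
                   6476800.0, 2073600.0)


def build_rpl30(s0: int = RPL30_DEFAULTS["s0"], y0: int | None = None,
                k: float = RPL30_DEFAULTS["k"], D: float = RPL30_DEFAULTS["D"],
                n: int = RPL30_DEFAULTS["n"]) -> System:
    """Reduced mRNA-decay model with ``y0`` transcripts already shortening.

    ``s0`` total transcripts split into x10 = s0 - y0 full-length molecules
    and ``y0`` imaginary molecules whose completions are pre-scheduled
    uniformly on [0, MT] with MT = delay(x10, y0, k, n)/D; the factor D > 1
    reflects that partially shortened transcripts finish early.  ``y0``
    defaults to the estimated imaginary fraction 23% of ``s0``.
    """
    if y0 is None:
        y0 = round(s0 * RPL30_DEFAULTS["y0"] / RPL30_DEFAULTS["s0"])
    if not 0 <= y0 <= s0:
        raise ValueError("need 0 <= y0 <= s0")
    if not k > 0:
        raise ValueError("k must be > 0")
    if not D > 1:
        raise ValueError("D must be > 1")
    x10 = int(s0) - int(y0)
    preload = []
    if y0 > 0:
        if x10 < 1:
            raise ValueError("pre-scheduling needs at least one full-length "
                             "molecule (y0 < s0)")
        MT = tau2_robust(DelayState(x10, int(y0), k, n)) / D
        preload = [("decay", int(y0), MT)]
    decay = Channel(
        name="decay",
        propensity=mass_action(k, "X1"),
        nu={"X1": -1, "G": +1},
        u={"G": -1, "P": +1},
        delay=state_dependent_delay("X1", k=k, n=n),
        imaginary="G",
    )
    return System(species=("X1", "G", "P"), initial={"X1": x10},
                  channels=[decay], preload=preload, time_unit="min")


def rpl30_chain_twin(s0: int = RPL30_DEFAULTS["s0"],
                     y0: int = RPL30_DEFAULTS["y0"],
                     k: float = RPL30_DEFAULTS["k"],
                     n: int = RPL30_DEFAULTS["n"]) -> ChainSpec:
    """The full multistep chain the reduced RPL30 model approximates."""
    return ChainSpec(n=n, k=k, x10=int(s0) - int(y0), y0=int(y0))


def ndd1_pulse(amplitude: float = 10.0, peak: float = 25.0,
               width: float = 30.0, cycle_len: float = 75.0,
               gate: float = 49.0):
    """Synthetic periodic NDD1 activity: raised-cosine pulse per cell cycle.

    Peaks during S phase and is forced to zero after minute ``gate`` of
    each cycle (mitosis terminates transcription).  Stand-in for the
    inferred single-cell activity profile, which is not packaged here.
    """

    def profile(t: float) -> float:
        phase = t % cycle_len
        if phase > gate:
            return 0.0
        d = phase - peak
        if abs(d) > width / 2:
            return 0.0
        return amplitude * 0.5 * (1.0 + math.cos(math.pi * d / (width / 2)))

    return profile


def build_swi5(a: float = SWI5_DEFAULTS["a"], b: float = SWI5_DEFAULTS["b"],
               tau_tx: float = SWI5_DEFAULTS["tau_tx"],
               tau_loc: float = SWI5_DEFAULTS["tau_loc"],
               k2: float = SWI5_DEFAULTS["k2"],
               k3: float = SWI5_DEFAULTS["k3"],
               ndd1_profile=None, cycle_len: float = 75.0,
               gate: float = 49.0, n_decay: int = 9) -> System:
    """Delayed SWI5 expression model.

    Transcription fires at the saturating activator rate
    a*[NDD1](t)/(b + [NDD1](t)) and manifests a nuclear mRNA after the
    constant elongation delay ``tau_tx``; translocation (rate k2 per
    nuclear mRNA) manifests a cytosolic mRNA after ``tau_loc``; cytosolic
    decay (rate k3) is the state-dependent-delay reduction of an
    ``n_decay``-step degradation chain.  [NDD1] is zeroed after minute
    ``gate`` of each ``cycle_len``-minute cycle.
    """
    for name, val in (("a", a), ("b", b), ("tau_tx", tau_tx),
                      ("tau_loc", tau_loc), ("k2", k2), ("k3", k3)):
        if not val > 0:
            raise ValueError(f"{name} must be > 0")
    if ndd1_profile is None:
        ndd1_profile = ndd1_pulse(cycle_len=cycle_len, gate=gate)

    def tx_rate(t: float) -> float:
        phase = t % cycle_len
        if phase > gate:
            return 0.0
        p = ndd1_profile(t)
        return a * p / (b + p) if p > 0 else 0.0

    transcription = Channel(
        name="transcription",
        propensity=time_varying(tx_rate),
        nu={"I1": +1},
        u={"I1": -1, "mRNA_N": +1},
        delay=constant_delay(tau_tx),
        imaginary="I1",
    )
    translocation = Channel(
        name="translocation",
        propensity=mass_action(k2, "mRNA_N"),
        nu={"mRNA_N": -1, "I2": +1},
        u={"I2": -1, "mRNA_C": +1},
        delay=constant_delay(tau_loc),
        imaginary="I2",
    )
    degradation = Channel(
        name="degradation",
        propensity=mass_action(k3, "mRNA_C"),
        nu={"mRNA_C": -1, "I3": +1},
        u={"I3": -1},
        delay=state_dependent_delay("mRNA_C", k=k3, n=n_decay),
        imaginary="I3",
    )
    return System(
        species=("mRNA_N", "mRNA_C", "I1", "I2", "I3"),
        initial={},
        channels=[transcription, translocation, degradation],
        time_unit="min",
    )


def build_glucosinolate(E1_0: int = 100,
                        V: tuple[float, ...] = GLUCOSINOLATE_V,
                        K: tuple[float, ...] = GLUCOSINOLATE_K,
                        reduced: str = "full",
                        const_delay: float = 3_000_000.0) -> System:
    """Six-step Michaelis-Menten elongation pathway E1 -> ... -> E7.

    ``reduced`` selects the variant: ``"full"`` simulates all six
    saturating conversions; ``"state"`` keeps the first conversion and
    lumps steps 2..6 into a state-dependent delay driven by the
    harmonic-mean effective rate; ``"constant"`` is the constant-delay
    baseline (default 3e6 time units).
    """
    if E1_0 < 0:
        raise ValueError("E1_0 must be >= 0")
    if len(V) != 6 or len(K) != 6:
        raise ValueError("V and K must list the six step parameters")
    if reduced == "full":
        species = tuple(f"E{i}" for i in range(1, 8))
        channels = [
            Channel(name=f"step{i}",
                    propensity=michaelis_menten(V[i - 1], K[i - 1], f"E{i}"),
                    nu={f"E{i}": -1, f"E{i + 1}": +1})
            for i in range(1, 7)
        ]
        return System(species=species, initial={"E1": int(E1_0)},
                      channels=channels)
    if reduced == "state":
        delay = state_dependent_delay("E1", mm=MMParams(V[1:], K[1:]), n=6)
    elif reduced == "constant":
        delay = constant_delay(const_delay)
    else:
        raise ValueError("reduced must be 'full', 'state' or 'constant'")
    lumped = Channel(
        name="elongation",
        propensity=michaelis_menten(V[0], K[0], "E1"),
        nu={"E1": -1, "U": +1},
        u={"U": -1, "E7": +1},
        delay=delay,
        imaginary="U",
    )
    return System(species=("E1", "U", "E7"), initial={"E1": int(E1_0)},
                  channels=[lumped])
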