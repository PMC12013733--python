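"""Mono- and bi-exponential off-kinetics curves.

After heavy exercise, pulmonary oxygen uptake decays from its end-exercise
peak back toward the resting baseline.  The decay is modeled as

    mono:  VO2(t) = baseline + A  · exp(-(t - td)/tau)
    bi:    VO2(t) = baseline + A1 · exp(-(t - td)/tau1)
                             + A2 · exp(-(t - td)/tau2)

with a single shared time delay ``td`` (seconds between exercise cessation
and the onset of the decline).  For ``t < td`` the exponent would be
positive; both curves are clamped to their value at ``td`` (a plateau at
``baseline + ΣA``) so early breaths neither explode nor must be discarded.

Amplitudes and baseline are in mL/min (or mL/kg/min in relative mode); time
constants in seconds; integrals are returned in litres of O₂.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

ML_MIN_S_PER_L = 60_000.0  # (mL/min)·s per litre of O2


@dataclass(frozen=True)
class MonoParams:
    """Mono-exponential parameter set.

    baseline : resting VO2 (asymptote), mL/min
    A        : recovery amplitude, mL/min
    td       : time delay, s
    tau      : time constant, s (time to complete 63.2% of the amplitude)
    """

    baseline: float
    A: float
    td: float
    tau: float

    def __post_init__(self) -> None:
        if self.baseline < 0 or self.A < 0 or self.td < 0:
            raise ValueError("baseline, A and td must be nonnegative")
        if self.tau <= 0:
            raise ValueError("tau must be positive")

    @property
    def amplitudes(self) -> tuple[float, ...]:
        return (self.A,)

    @property
    def taus(self) -> tuple[float, ...]:
        return (self.tau,)

    def to_dict(self) -> dict[str, float]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "MonoParams":
        return cls(**{k: float(d[k]) for k in ("baseline", "A", "td", "tau")})


@dataclass(frozen=True)
class BiParams:
    """Bi-exponential parameter set: fast phase (A1, tau1) + slow phase
    (A2, tau2) sharing one time delay ``td``.
    """

    baseline: float
    A1: float
    td: float
    tau1: float
    A2: float
    tau2: float

    def __post_init__(self) -> None:
        if min(self.baseline, self.A1, self.A2, self.td) < 0:
            raise ValueError("baseline, A1, A2 and td must be nonnegative")
        if self.tau1 <= 0 or self.tau2 <= 0:
            raise ValueError("time constants must be positive")
        if self.tau1 >= self.tau2:
            raise ValueError("phase ordering requires tau1 < tau2")

    @property
    def amplitudes(self) -> tuple[float, ...]:
        return (self.A1, self.A2)

    @property
    def taus(self) -> tuple[float, ...]:
        return (self.tau1, self.tau2)

    def to_dict(self) -> dict[str, float]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "BiParams":
        keys = ("baseline", "A1", "td", "tau1", "A2", "tau2")
        return cls(**{k: float(d[k]) for k in keys})


Params = MonoParams | BiParams


def _clamped_elapsed(t: np.ndarray, td: float) -> np.ndarray:
    return np.maximum(np.asarray(t, dtype=float) - td, 0.0)


def eval_mono(p: MonoParams, t) -> np.ndarray:
    """Evaluate the clamped mono-exponential at times ``t`` (seconds)."""
    s = _clamped_elapsed(t, p.td)
    return p.baseline + p.A * np.exp(-s / p.tau)


def eval_bi(p: BiParams, t) -> np.ndarray:
    """Evaluate the clamped bi-exponential at times ``t`` (seconds)."""
    s = _clamped_elapsed(t, p.td)
    return (
        p.baseline
        + p.A1 * np.exp(-s / p.tau1)
        + p.A2 * np.exp(-s / p.tau2)
    )


def eval_params(p: Params, t) -> np.ndarray:
    return eval_mono(p, t) if isinstance(p, MonoParams) else eval_bi(p, t)


def curve_integral(p: Params, t0: float, t1: float) -> float:
    """Closed-form integral of the clamped model over [t0, t1], in L O₂.

    The plateau segment (t < td) contributes (baseline + ΣA)·Δt; past the
    delay each phase contributes A·tau·(e^{-s0/tau} - e^{-s1/tau}) with s
    the clamped elapsed time; baseline contributes baseline·(t1 - t0).
    Conversion: (mL/min)·s → L is a division by 60 000.
    """
    if not (0 <= t0 < t1):
        raise ValueError(f"need 0 <= t0 < t1, got [{t0}, {t1}]")
    total = p.baseline * (t1 - t0)
    for a, tau in zip(p.amplitudes, p.taus):
        plateau = max(min(t1, p.td) - t0, 0.0)  # portion before the delay
        s0 = max(t0 - p.td, 0.0)
        s1 = t1 - p.td
        decay = a * tau * (np.exp(-s0 / tau) - np.exp(-s1 / tau)) if s1 > 0 else 0.0
        total += a * plateau + decay
    return float(total) / ML_MIN_S_PER_L
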