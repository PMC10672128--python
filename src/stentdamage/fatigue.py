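"""Fatigue damage under pulsatile loading: Basquin S-N life + Miner's rule.

The implanted stent sees a pulsatile blood-pressure cycle (default
100 +/- 20 mmHg, i.e. 80-120 mmHg) at cardiac frequency.  The number of
cycles to failure at stress amplitude sigma follows Basquin's power law

    N(sigma) = A * sigma^(-k)        (log N linear in log sigma)

and damage accumulates linearly by Miner's rule: each time step of length dt
at stress sigma contributes

    dD_f = n_t / N_t = f * dt / N(sigma)

with f the loading frequency in cycles/hour.  Because the element's stress
changes as it degrades, the per-step quotients track a variable-amplitude
history; failure of the fatigue channel alone corresponds to sum = 1.

The Basquin constants default to A = 1e12 MPa^k cycles, k = 3 — placeholder
values of a generic S-N curve, NOT calibrated to a measured zinc-alloy curve;
supply alloy-specific constants for quantitative life prediction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np


@dataclass(frozen=True)
class FatigueParams:
    """Basquin coefficients and loading frequency.

    A : Basquin coefficient, MPa^k * cycles
    k : Basquin exponent (dimensionless)
    frequency : cycles per hour (default 4320 = 1.2 Hz, ~72 bpm heart rate)
    sigma_floor : MPa; below it dD_f = 0 (0 disables the floor, pure Basquin)
    enabled : master switch (fatigue acts only in the coupled group)
    """

    A: float = 1e12
    k: float = 3.0
    frequency: float = 4320.0
    sigma_floor: float = 0.0
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.A <= 0 or self.k <= 0 or self.frequency <= 0:
            raise ValueError("A, k and frequency must be strictly positive")
        if self.sigma_floor < 0:
            raise ValueError("sigma_floor must be non-negative")


@dataclass(frozen=True)
class LoadWaveform:
    """Pulsatile pressure waveform: base +/- amplitude, in mmHg."""

    base_pressure: float = 100.0
    amplitude: float = 20.0
    shape: str = "sinusoidal"

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.base_pressure <= self.amplitude:
            raise ValueError("base_pressure must exceed amplitude (pressure never negative)")


def waveform_extrema(w: LoadWaveform) -> tuple[float, float]:
    """(min, max) pressure of the cycle = (base - amplitude, base + amplitude)."""
    return (w.base_pressure - w.amplitude, w.base_pressure + w.amplitude)


def basquin_life(sigma: float | np.ndarray, p: FatigueParams) -> float | np.ndarray:
    """Cycles to failure N = A * sigma^(-k); strictly decreasing in sigma."""
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be strictly positive")
    out = p.A * sigma ** (-p.k)
    return float(out) if out.ndim == 0 else out


def fatigue_increment(sigma: float | np.ndarray, dt: float, p: FatigueParams) -> float | np.ndarray:
    """Miner damage accrued in dt hours at constant stress sigma:
    (frequency * dt) / N(sigma).  Zero when disabled or below sigma_floor."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    sigma = np.asarray(sigma, dtype=float)
    if not p.enabled:
        out = np.zeros_like(sigma)
        return float(out) if out.ndim == 0 else out
    cycles = p.frequency * dt
    safe = np.where(sigma > max(p.sigma_floor, 0.0), sigma, 1.0)
    out = np.where(sigma > max(p.sigma_floor, 0.0), cycles / basquin_life(safe, p), 0.0)
    return float(out) if out.ndim == 0 else out


def miner_accumulate(increments: Iterable[float]) -> float:
    """Miner linear accumulation: the plain (order-independent) sum of
    per-block damage quotients n_i / N_i; failure at 1."""
    total = 0.0
    for inc in increments:
        if inc < 0:
            raise ValueError("damage increments must be non-negative")
        total += inc
    return total
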