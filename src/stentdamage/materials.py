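"""Zinc-alloy material constants and the continuum-damage relations.

Continuum damage mechanics (CDM) represents distributed material loss by a
scalar damage field D in [0, 1] per element: D = 0 pristine, D = 1 failed
(the element is removed from the mesh).  Total damage is the linear
superposition of four mechanisms

    D = D_U + D_SC + D_P + D_f

(uniform corrosion, stress corrosion, pitting, fatigue).  Under the strain
equivalence hypothesis both the load-bearing stress and the Young's modulus
are discounted linearly by damage:

    sigma = sigma_bar * (1 - D),    E = E_bar * (1 - D)

so the elastic strain sigma/E = sigma_bar/E_bar is invariant while the
element's mechanical integrity decays to zero.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class MaterialParams:
    """Mechanical constants of the stent alloy.

    Defaults are the zinc-alloy values used throughout: density 8.5 g/cm^3,
    E = 74,500 MPa, nu = 0.3, yield 220 MPa, ultimate 325 MPa.
    """

    density: float = 8.5            # g/cm^3
    youngs_modulus: float = 74_500.0  # MPa, undamaged
    poisson_ratio: float = 0.3
    yield_strength: float = 220.0   # MPa
    ultimate_strength: float = 325.0  # MPa

    def __post_init__(self) -> None:
        if min(self.density, self.youngs_modulus, self.yield_strength, self.ultimate_strength) <= 0:
            raise ValueError("material constants must be strictly positive")
        if not 0.0 < self.poisson_ratio < 0.5:
            raise ValueError("poisson_ratio must lie in (0, 0.5)")
        if self.yield_strength >= self.ultimate_strength:
            raise ValueError("yield_strength must be below ultimate_strength")


@dataclass
class DamageComponents:
    """Per-element damage split by mechanism; each component is non-negative
    and non-decreasing over a run."""

    D_U: float = 0.0
    D_SC: float = 0.0
    D_P: float = 0.0
    D_f: float = 0.0

    def __post_init__(self) -> None:
        for name in ("D_U", "D_SC", "D_P", "D_f"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def total_damage(c: DamageComponents) -> float:
    """Linear superposition D_U + D_SC + D_P + D_f, clamped to 1 for
    reporting (deletion triggers at D >= 1)."""
    return min(1.0, c.D_U + c.D_SC + c.D_P + c.D_f)


def discounted_stress(sigma_bar: float, D: float) -> float:
    """Effective stress carried by a damaged element: sigma_bar * (1 - D)."""
    if not 0.0 <= D <= 1.0:
        raise ValueError("damage D must lie in [0, 1]")
    return sigma_bar * (1.0 - D)


def degraded_modulus(E_bar: float, D: float) -> float:
    """Damaged Young's modulus E_bar * (1 - D); strain equivalence holds:
    discounted_stress(s, D) / degraded_modulus(E, D) == s / E for D < 1."""
    if not 0.0 <= D <= 1.0:
        raise ValueError("damage D must lie in [0, 1]")
    return E_bar * (1.0 - D)


def stress_corrosion_threshold(m: MaterialParams, fraction: float = 0.30) -> float:
    """Stress-corrosion threshold sigma_th as a fraction of the yield
    strength (default 30%, the low end of the commonly used 30%-of-yield to
    90%-of-ultimate range; 0.30 x 220 MPa = 66 MPa for the default alloy)."""
    if fraction < 0:
        raise ValueError("fraction must be non-negative")
    return fraction * m.yield_strength
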