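"""Corrosion rate laws: uniform, stress-driven, and pitting.

All three mechanisms are expressed as damage rates dD/dt (per hour) for a
single element of characteristic length Le:

* uniform corrosion   dD_U/dt  = (delta_U / Le) * k_U        (exposed only)
* stress corrosion    dD_SC/dt = (Le / delta_SC) * S * sigma_eq / (1 - D_SC)^R
                      gated to zero below the threshold sigma_th
                      (any alive element, exposed or not)
* pitting corrosion   dD_P/dt  = (delta_U / Le) * lambda_e * k_U  (exposed only)

The pitting intensity lambda_e is drawn once per initially exposed element
from a Weibull distribution; when a pitted element is removed, each newly
exposed neighbour inherits lambda_e = beta * lambda_n, so pits propagate into
the bulk, accelerated (beta > 1) or damped (beta < 1).

Default kinetic constants: delta_U = 0.1 mm, k_U = 0.05/h, delta_SC = 0.07 mm,
S = 0.005 mm^2 h/N, R = 2, sigma_th = 66 MPa, beta = 0.8.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np

from .errors import StateError


@dataclass(frozen=True)
class CorrosionParams:
    """Kinetic constants of the three corrosion mechanisms."""

    delta_U: float = 0.1       # mm, uniform-corrosion feature size
    k_U: float = 0.05          # 1/h, uniform kinetic parameter
    delta_SC: float = 0.07     # mm, stress-corrosion feature size
    S: float = 0.005           # mm^2 h / N, stress-corrosion kinetic constant
    R: float = 2.0             # dimensionless exponent (damage feedback)
    sigma_th: float = 66.0     # MPa, stress-corrosion threshold
    beta: float = 0.8          # dimensionless pit-propagation factor
    weibull_shape: float = 1.0
    weibull_scale: float = 1.0
    pitting_enabled: bool = True
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("delta_U", "delta_SC", "weibull_shape", "weibull_scale", "beta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        # k_U = 0 / S = 0 switch the corresponding channel off
        for name in ("k_U", "S", "R"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


class StressTensor6(NamedTuple):
    """Six-component Cauchy stress (MPa): normals sx, sy, sz and shears
    txy, tyz, tzx."""

    sx: float
    sy: float
    sz: float
    txy: float = 0.0
    tyz: float = 0.0
    tzx: float = 0.0


def von_mises(t: StressTensor6 | np.ndarray) -> float | np.ndarray:
    """Von Mises equivalent stress.

    sigma_eq = sqrt(0.5 * [(sx-sy)^2 + (sy-sz)^2 + (sz-sx)^2]
                    + 3 * (txy^2 + tyz^2 + tzx^2))

    Accepts a single StressTensor6 or an (..., 6) array.  Zero for
    hydrostatic states; equals |sx| for uniaxial tension.
    """
    a = np.asarray(t, dtype=float)
    sx, sy, sz, txy, tyz, tzx = np.moveaxis(a, -1, 0)
    s = 0.5 * ((sx - sy) ** 2 + (sy - sz) ** 2 + (sz - sx) ** 2) + 3.0 * (txy**2 + tyz**2 + tzx**2)
    out = np.sqrt(s)
    return float(out) if out.ndim == 0 else out


def uniform_rate(Le: float | np.ndarray, p: CorrosionParams) -> float | np.ndarray:
    """Uniform-corrosion damage rate (delta_U / Le) * k_U, per hour.

    The per-element rate scales inversely with Le so the corrosion front
    speed delta_U * k_U (mm/h) is mesh-independent.  The engine applies it
    to exposed elements only.
    """
    Le = np.asarray(Le, dtype=float)
    if np.any(Le <= 0):
        raise ValueError("Le must be strictly positive")
    out = (p.delta_U / Le) * p.k_U
    return float(out) if out.ndim == 0 else out


def stress_corrosion_rate(
    sigma_eq: float | np.ndarray,
    D_SC: float | np.ndarray,
    Le: float | np.ndarray,
    p: CorrosionParams,
) -> float | np.ndarray:
    """Stress-corrosion damage rate, per hour.

    Zero below the threshold sigma_th; otherwise
    (Le / delta_SC) * S * sigma_eq / (1 - D_SC)^R, which accelerates as the
    stress-corrosion damage itself accumulates (positive feedback through
    the (1 - D_SC)^-R factor).
    """
    sigma_eq = np.asarray(sigma_eq, dtype=float)
    D_SC = np.asarray(D_SC, dtype=float)
    Le = np.asarray(Le, dtype=float)
    if np.any(Le <= 0):
        raise ValueError("Le must be strictly positive")
    if np.any(D_SC < 0) or np.any(D_SC >= 1.0):
        raise StateError("D_SC must lie in [0, 1); fully damaged elements should be deleted")
    rate = (Le / p.delta_SC) * p.S * sigma_eq / (1.0 - D_SC) ** p.R
    out = np.where(sigma_eq < p.sigma_th, 0.0, rate)
    return float(out) if out.ndim == 0 else out


def assign_pitting_params(
    surface: Iterable[int],
    p: CorrosionParams,
    rng: np.random.Generator | None = None,
) -> dict[int, float]:
    """Draw an independent Weibull(shape, scale) pitting intensity lambda_e
    for each initially exposed element.

    Reproducible: with no explicit generator, a fresh Generator is seeded
    from ``p.rng_seed``.  Elements not on the initial surface carry
    lambda_e = 0 until they inherit a value through pit propagation.
    """
    surface = sorted(int(e) for e in surface)
    if not surface:
        raise ValueError("surface element set must be non-empty")
    if rng is None:
        rng = np.random.default_rng(p.rng_seed)
    draws = p.weibull_scale * rng.weibull(p.weibull_shape, size=len(surface))
    return {e: float(l) for e, l in zip(surface, draws)}


def pitting_rate(
    Le: float | np.ndarray, lambda_e: float | np.ndarray, p: CorrosionParams
) -> float | np.ndarray:
    """Pitting damage rate (delta_U / Le) * lambda_e * k_U, per hour.

    Identical to the uniform law scaled by the local pit intensity;
    lambda_e = 1 reproduces uniform_rate exactly, lambda_e = 0 means no pit.
    """
    Le = np.asarray(Le, dtype=float)
    lambda_e = np.asarray(lambda_e, dtype=float)
    if np.any(Le <= 0):
        raise ValueError("Le must be strictly positive")
    if np.any(lambda_e < 0):
        raise ValueError("lambda_e must be non-negative")
    out = (p.delta_U / Le) * lambda_e * p.k_U
    return float(out) if out.ndim == 0 else out


def propagate_pitting(lambda_n: float, p: CorrosionParams) -> float:
    """Pit intensity inherited by a newly exposed neighbour of a removed
    pitted element: lambda_e = beta * lambda_n.  When several removed
    neighbours border the element, the engine passes the largest lambda_n
    (growth is dominated by the deepest adjacent pit)."""
    if lambda_n < 0:
        raise ValueError("lambda_n must be non-negative")
    return p.beta * lambda_n
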