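"""Per-element stress supply: residual field, pulsatile scaling, damage discount.

The degradation model starts from the residual stress field left in the stent
after balloon expansion and elastic recoil.  That field enters this package
as *data* — either a per-element table of six-component tensors or a built-in
analytic field reproducing the qualitative topology of a deployed ring stent
(stress concentrated at the crown bends, decaying into the straight struts).

During a run the frozen residual field is modified multiplicatively:

* pulsatile groups scale it by P_peak / P_ref, evaluating rates at the
  per-cycle peak pressure (quasi-static peak-pressure scaling);
* damage discounts the tensor by (1 - D), so the effective stress of every
  element decays linearly as it degrades;
* optionally, a stress-concentration factor kappa >= 1 is applied to exposed
  elements that border deleted elements, a phenomenological stand-in for the
  load redistribution a full FE re-solve would capture (off by default).
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass

import numpy as np

from .corrosion import StressTensor6, von_mises
from .errors import FormatError
from .fatigue import LoadWaveform, waveform_extrema
from .mesh import HexMesh

logger = logging.getLogger(__name__)

GROUPS = ("C1", "E1", "E2")


@dataclass
class ResidualStressField:
    """Frozen per-element residual stress tensors at a reference pressure.

    tensors : (n_elem, 6) array, MPa — sx, sy, sz, txy, tyz, tzx
    reference_pressure : mmHg at which the residual field is defined
    """

    tensors: np.ndarray
    reference_pressure: float = 100.0

    def __post_init__(self) -> None:
        self.tensors = np.asarray(self.tensors, dtype=float)
        if self.tensors.ndim != 2 or self.tensors.shape[1] != 6:
            raise FormatError("stress field must be an (n, 6) array")
        if not np.all(np.isfinite(self.tensors)):
            raise FormatError("stress field contains non-finite values")
        if self.reference_pressure <= 0:
            raise ValueError("reference_pressure must be positive")

    @property
    def n_elements(self) -> int:
        return self.tensors.shape[0]

    def von_mises(self) -> np.ndarray:
        """Equivalent stress of the raw residual tensors, per element."""
        return von_mises(self.tensors)


def load_stress_field(
    table: np.ndarray, n_elements: int, reference_pressure: float = 100.0
) -> ResidualStressField:
    """Validate a per-element stress table and bind it to a mesh size.

    Accepts an (n, 6) tensor table or an (n,) / (n, 1) scalar column of
    equivalent stresses; scalars are embedded as uniaxial tensors
    (sx = sigma, all other components zero), which preserves their von Mises
    value.
    """
    a = np.asarray(table, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    if a.shape[0] != n_elements:
        raise FormatError(f"stress table has {a.shape[0]} records for {n_elements} elements")
    if not np.all(np.isfinite(a)):
        raise FormatError("stress table contains non-finite values")
    if a.shape[1] == 6:
        tensors = a
    elif a.shape[1] == 1:
        logger.info("scalar stress records embedded as uniaxial tensors (sx = sigma)")
        tensors = np.zeros((n_elements, 6))
        tensors[:, 0] = a[:, 0]
    else:
        raise FormatError(f"stress records must have 1 or 6 components, got {a.shape[1]}")
    return ResidualStressField(tensors=tensors, reference_pressure=reference_pressure)


def analytic_crown_field(
    mesh: HexMesh,
    peak_stress: float = 230.0,
    decay: float = 0.5,
    reference_pressure: float = 100.0,
) -> ResidualStressField:
    """Synthetic post-deployment residual field for a labelled ring mesh.

    Elements in the "corolla" set carry the uniaxial peak stress; stress
    decays geometrically with face-graph distance d into the struts,
    sigma(d) = peak_stress * decay^d.  This reproduces the qualitative
    stress topology of a deployed stent — bending stress concentrated at
    the crowns — without running the deployment FE stage.
    """
    if "corolla" not in mesh.element_set_labels:
        raise ValueError('mesh has no "corolla" element set; use the ring generator or label a high-stress set')
    if not 0.0 < decay <= 1.0:
        raise ValueError("decay must lie in (0, 1]")
    sources = mesh.element_set_labels["corolla"]
    dist = np.full(mesh.n_elements, -1, dtype=np.int64)
    queue = deque(int(e) for e in sources)
    dist[sources] = 0
    while queue:
        e = queue.popleft()
        for nb in mesh.face_adjacency[e]:
            if nb >= 0 and dist[nb] < 0:
                dist[nb] = dist[e] + 1
                queue.append(int(nb))
    dist[dist < 0] = dist.max() + 1 if np.any(dist >= 0) else 0
    sigma = peak_stress * np.asarray(decay, dtype=float) ** dist
    tensors = np.zeros((mesh.n_elements, 6))
    tensors[:, 0] = sigma
    return ResidualStressField(tensors=tensors, reference_pressure=reference_pressure)


def pressure_scale(w: LoadWaveform, reference_pressure: float, mode: str) -> float:
    """Multiplicative stress factor for a group: 1 for the corrosion-only
    control, P_peak / P_ref for the pulsatile groups (rates evaluated at the
    cyclic peak pressure)."""
    if mode not in GROUPS:
        raise ValueError(f"unknown group {mode!r}; expected one of {GROUPS}")
    if mode == "C1":
        return 1.0
    _, p_peak = waveform_extrema(w)
    return p_peak / reference_pressure


def stress_at(
    element: int,
    t: float,
    field: ResidualStressField,
    w: LoadWaveform,
    D: float,
    mode: str,
) -> StressTensor6:
    """Stress tensor of one element at simulation time t (hours).

    The frozen residual tensor is scaled by the group's pressure factor and
    discounted by (1 - D); at D = 1 the element carries no stress.  The
    field is static, so t enters only through D (kept in the signature for
    future time-varying fields).
    """
    if not 0.0 <= D <= 1.0:
        raise ValueError("damage D must lie in [0, 1]")
    scale = pressure_scale(w, field.reference_pressure, mode) * (1.0 - D)
    return StressTensor6(*(scale * field.tensors[element]))
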