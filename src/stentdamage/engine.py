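"""Explicit time-stepping loop coupling corrosion and fatigue damage.

Each step, for every alive element:

1. the driving stress is computed from the frozen residual tensor, scaled
   by the group's pulsatile peak-pressure factor and optionally amplified by
   the stress-concentration factor kappa on exposed elements bordering
   deleted ones (the damage discount applies to the reported effective
   stress, not to the driving stress — see :func:`driving_sigma_eq`);
2. damage rates are accrued — uniform and pitting corrosion on exposed
   elements, stress corrosion on any alive element above the threshold,
   fatigue (coupled group only) on exposed elements;
3. components are advanced by explicit Euler; every element whose total
   damage reaches 1 is deleted simultaneously at the end of the step;
4. exposure is recomputed and newly exposed elements inherit pitting
   intensity beta * max(lambda of the removed face-neighbours).

Groups: C1 = corrosion only at the reference pressure; E1 = corrosion with
pulsatile peak-pressure scaling; E2 = E1 plus fatigue damage.

Mass loss is the removed-volume fraction (density is uniform, so volume
fraction equals mass fraction).  Structural fracture — loss of
face-connectivity of the alive elements — is recorded at its first
occurrence but the run continues to t_max, since the severed pieces keep
corroding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np

from .corrosion import CorrosionParams, assign_pitting_params
from .fatigue import FatigueParams, LoadWaveform
from .materials import MaterialParams
from .mesh import HexMesh, exposure_mask, is_fractured
from .stress import GROUPS, ResidualStressField, pressure_scale

logger = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    """Fully resolved run configuration (one experiment group)."""

    group: str = "C1"
    dt: float = 0.1                # hours
    t_max: float = 100.0           # hours
    snapshot_interval: float = 0.0  # hours; 0 disables snapshots
    kappa: float = 1.0             # stress-concentration factor, 1 = off
    rng_seed: int | None = None
    material: MaterialParams = dc_field(default_factory=MaterialParams)
    corrosion: CorrosionParams = dc_field(default_factory=CorrosionParams)
    fatigue: FatigueParams = dc_field(default_factory=FatigueParams)
    waveform: LoadWaveform = dc_field(default_factory=LoadWaveform)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.t_max < self.dt:
            raise ValueError("t_max must be at least dt")
        if self.kappa < 1.0:
            raise ValueError("kappa must be >= 1")

    @property
    def fatigue_active(self) -> bool:
        return self.group == "E2" and self.fatigue.enabled


@dataclass
class EngineState:
    """Mutable per-element state advanced by :func:`step`."""

    mesh: HexMesh
    field: ResidualStressField
    config: SimulationConfig
    time: float = 0.0
    alive: np.ndarray = None  # bool (n,)
    exposed: np.ndarray = None  # bool (n,)
    D_U: np.ndarray = None
    D_SC: np.ndarray = None
    D_P: np.ndarray = None
    D_f: np.ndarray = None
    lam: np.ndarray = None  # pitting intensity per element
    removed_log: list[tuple[float, int]] = dc_field(default_factory=list)

    @property
    def D_total(self) -> np.ndarray:
        return self.D_U + self.D_SC + self.D_P + self.D_f

    def damage_clamped(self) -> np.ndarray:
        return np.minimum(1.0, self.D_total)


def init_state(mesh: HexMesh, field: ResidualStressField, config: SimulationConfig) -> EngineState:
    """Pristine state: all alive, initial surface exposed, Weibull pitting
    intensities drawn on that surface."""
    if field.n_elements != mesh.n_elements:
        raise ValueError(
            f"stress field has {field.n_elements} records for a mesh of {mesh.n_elements} elements"
        )
    n = mesh.n_elements
    alive = np.ones(n, dtype=bool)
    exposed = exposure_mask(mesh, alive)
    lam = np.zeros(n)
    if config.corrosion.pitting_enabled:
        if config.rng_seed is None and config.corrosion.rng_seed is None:
            raise ValueError("rng_seed is required when pitting is enabled")
        seed = config.corrosion.rng_seed if config.corrosion.rng_seed is not None else config.rng_seed
        rng = np.random.default_rng(seed)
        surface = np.flatnonzero(exposed)
        draws = assign_pitting_params(surface, config.corrosion, rng=rng)
        for e, l in draws.items():
            lam[e] = l
    return EngineState(
        mesh=mesh, field=field, config=config,
        alive=alive, exposed=exposed,
        D_U=np.zeros(n), D_SC=np.zeros(n), D_P=np.zeros(n), D_f=np.zeros(n),
        lam=lam,
    )


def driving_sigma_eq(state: EngineState) -> np.ndarray:
    """Von Mises stress driving the rate laws, per element: the residual
    field scaled by the group's pulsatile peak-pressure factor and by the
    kappa concentration on exposed elements bordering deleted ones.

    Deliberately NOT discounted by damage: in this frozen-field model the
    load an element sheds as it damages is carried by the surrounding
    material of the same region, so the stress available to drive corrosion
    and fatigue there does not vanish with the element's own integrity
    (damaged regions accelerate, they do not self-quench).  The damage
    discount applies to the *reported* effective stress instead
    (:func:`effective_sigma_eq`).
    """
    cfg = state.config
    vm0 = state.field.von_mises()
    scale = pressure_scale(cfg.waveform, state.field.reference_pressure, cfg.group)
    sigma = vm0 * scale
    if cfg.kappa > 1.0:
        adj = state.mesh.face_adjacency
        valid = adj >= 0
        dead_nb = np.zeros(adj.shape, dtype=bool)
        dead_nb[valid] = ~state.alive[adj[valid]]
        has_dead_neighbor = dead_nb.any(axis=1)
        sigma = np.where(state.exposed & has_dead_neighbor, cfg.kappa * sigma, sigma)
    return np.where(state.alive, sigma, 0.0)


def effective_sigma_eq(state: EngineState) -> np.ndarray:
    """Damage-discounted von Mises stress per element — the material-
    integrity readout (decays linearly with D as the element degrades)."""
    return driving_sigma_eq(state) * (1.0 - state.damage_clamped())


def step(state: EngineState, dt: float | None = None) -> EngineState:
    """Advance the state by one explicit-Euler step (in place)."""
    cfg = state.config
    if dt is None:
        dt = cfg.dt
    if dt <= 0:
        raise ValueError("dt must be positive")
    p = cfg.corrosion
    mesh = state.mesh
    Le = mesh.characteristic_lengths()

    sigma_eq = driving_sigma_eq(state)
    alive, exposed = state.alive, state.exposed

    # uniform corrosion: exposed only
    dDU = np.where(exposed, (p.delta_U / Le) * p.k_U, 0.0)
    # pitting: exposed only, scaled by lambda_e
    dDP = np.where(exposed, (p.delta_U / Le) * state.lam * p.k_U, 0.0)
    # stress corrosion: any alive element above threshold
    dsc_safe = np.minimum(state.D_SC, 1.0 - 1e-12)
    rate_sc = (Le / p.delta_SC) * p.S * sigma_eq / (1.0 - dsc_safe) ** p.R
    dDSC = np.where(alive & (sigma_eq >= p.sigma_th), rate_sc, 0.0)
    # fatigue: exposed only, coupled group only
    if cfg.fatigue_active:
        f = cfg.fatigue
        floor = max(f.sigma_floor, 0.0)
        sig = np.where(sigma_eq > floor, sigma_eq, 1.0)
        dDf = np.where(exposed & (sigma_eq > floor), f.frequency * sig**f.k / f.A, 0.0)
    else:
        dDf = np.zeros_like(dDU)

    state.D_U += dDU * dt
    state.D_P += dDP * dt
    state.D_SC += dDSC * dt
    state.D_f += dDf * dt
    state.time += dt

    # simultaneous deletion of all elements reaching D >= 1
    dying = alive & (state.D_total >= 1.0)
    if np.any(dying):
        state.alive = alive & ~dying
        for e in np.flatnonzero(dying):
            state.removed_log.append((state.time, int(e)))
        was_exposed = state.exposed
        state.exposed = exposure_mask(mesh, state.alive)
        # pit propagation into newly exposed neighbours of removed elements
        newly = state.exposed & ~was_exposed
        if np.any(newly):
            adj = mesh.face_adjacency
            for e in np.flatnonzero(newly):
                nb = adj[e]
                removed_nb = nb[(nb >= 0) & dying[np.clip(nb, 0, None)]]
                if removed_nb.size:
                    lam_n = float(state.lam[removed_nb].max())
                    if lam_n > 0.0:
                        state.lam[e] = p.beta * lam_n
    return state


def mass_loss(mesh: HexMesh, alive: np.ndarray) -> float:
    """Removed volume fraction = removed mass fraction (uniform density)."""
    v = mesh.element_volume
    total = float(v.sum())
    return float(v[~np.asarray(alive, dtype=bool)].sum()) / total


def region_mean_effective_stress(elements, state: EngineState) -> float | None:
    """Mean damage-discounted equivalent stress over the alive elements of a
    region (a label from the mesh's element sets or an explicit index set).
    Returns None once the region has fully degraded."""
    if isinstance(elements, str):
        idx = state.mesh.element_set_labels[elements]
    else:
        idx = np.asarray(sorted(elements), dtype=np.int64)
    if idx.size == 0:
        raise ValueError("region must be non-empty")
    sigma = effective_sigma_eq(state)
    alive_idx = idx[state.alive[idx]]
    if alive_idx.size == 0:
        return None
    return float(sigma[alive_idx].mean())


@dataclass
class SimulationResult:
    """Time series and summary of one degradation run."""

    time_grid: np.ndarray
    mass_loss_fraction: np.ndarray
    removed_log: list[tuple[float, int]]
    fracture_time: float | None
    damage_snapshots: dict[float, dict[str, np.ndarray]]
    summary: dict

    @property
    def final_mass_loss(self) -> float:
        return float(self.mass_loss_fraction[-1])


def run(config: SimulationConfig, mesh: HexMesh, field: ResidualStressField) -> SimulationResult:
    """Run the degradation simulation from a pristine state to t_max (or
    until every element is gone).  Records the mass-loss series each step,
    the element-removal log, per-component damage snapshots, and the first
    fracture time (the run continues past fracture)."""
    state = init_state(mesh, field, config)
    times = [0.0]
    losses = [0.0]
    fracture_time: float | None = None
    snapshots: dict[float, dict[str, np.ndarray]] = {}
    next_snap = config.snapshot_interval if config.snapshot_interval > 0 else np.inf

    n_steps = int(round(config.t_max / config.dt))
    for _ in range(n_steps):
        n_dead_before = int((~state.alive).sum())
        step(state)
        times.append(state.time)
        losses.append(mass_loss(mesh, state.alive))
        n_dead = int((~state.alive).sum())
        if fracture_time is None and n_dead > n_dead_before and is_fractured(mesh, state.alive):
            fracture_time = state.time
        if state.time + 1e-9 >= next_snap:
            snapshots[state.time] = _snapshot(state)
            next_snap += config.snapshot_interval
        logger.debug(
            "t=%.3f h alive=%d mass_loss=%.4f maxD=%.3f",
            state.time, int(state.alive.sum()), losses[-1], float(state.damage_clamped().max()),
        )
        if not state.alive.any():
            break

    snapshots[state.time] = _snapshot(state)
    result = SimulationResult(
        time_grid=np.asarray(times),
        mass_loss_fraction=np.asarray(losses),
        removed_log=list(state.removed_log),
        fracture_time=fracture_time,
        damage_snapshots=snapshots,
        summary={
            "group": config.group,
            "final_time_h": state.time,
            "final_mass_loss": losses[-1],
            "n_removed": len(state.removed_log),
            "fracture_time_h": fracture_time,
            "D_U_total": float(state.D_U.sum()),
            "D_SC_total": float(state.D_SC.sum()),
            "D_P_total": float(state.D_P.sum()),
            "D_f_total": float(state.D_f.sum()),
        },
    )
    return result


def _snapshot(state: EngineState) -> dict[str, np.ndarray]:
    return {
        "D_U": state.D_U.copy(),
        "D_SC": state.D_SC.copy(),
        "D_P": state.D_P.copy(),
        "D_f": state.D_f.copy(),
        "D": state.damage_clamped(),
        "alive": state.alive.astype(float),
        "exposed": state.exposed.astype(float),
    }
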