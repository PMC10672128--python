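"""File formats and run configuration.

Readers: TOML/JSON run configuration, an Abaqus INP subset (*NODE,
*ELEMENT TYPE=C3D8R, *ELSET), delimited per-element stress tables.
Writers: the same INP subset, ASCII VTU snapshots with per-element scalar
fields, mass-loss CSV time series, and a JSON run manifest capturing every
resolved parameter so a run can be reproduced bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from .corrosion import CorrosionParams
from .engine import SimulationConfig, SimulationResult
from .errors import ConfigError, FormatError
from .fatigue import FatigueParams, LoadWaveform
from .materials import MaterialParams
from .mesh import HexMesh, make_mesh
from .stress import ResidualStressField, load_stress_field

logger = logging.getLogger(__name__)

_BLOCK_TYPES = {
    "material": MaterialParams,
    "corrosion": CorrosionParams,
    "fatigue": FatigueParams,
    "waveform": LoadWaveform,
}
_TOP_KEYS = {"group", "dt", "t_max", "snapshot_interval", "kappa", "rng_seed",
             "mesh", "stress"} | set(_BLOCK_TYPES)


def parse_config(path: str | Path) -> tuple[SimulationConfig, dict, dict]:
    """Parse a TOML (or JSON) run configuration.

    Omitted material/corrosion/fatigue/waveform fields resolve to the
    built-in defaults (the standard zinc-alloy constants and kinetic
    parameters).  Returns ``(config, mesh_block, stress_block)`` — the mesh
    and stress blocks are passed through for the CLI to build inputs from.

    Raises ConfigError with the offending field path on unknown keys,
    invariant violations, or a missing seed for a pitting-enabled run.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = tomllib.loads(text)
    return resolve_config(raw)


def resolve_config(raw: dict) -> tuple[SimulationConfig, dict, dict]:
    """Resolve a raw configuration mapping into a validated SimulationConfig."""
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    blocks = {}
    for name, cls in _BLOCK_TYPES.items():
        block = dict(raw.get(name, {}))
        valid_fields = {f.name for f in dataclasses.fields(cls)}
        bad = set(block) - valid_fields
        if bad:
            raise ConfigError(f"{name}.{sorted(bad)[0]}: unknown key")
        try:
            blocks[name] = cls(**block)
        except (ValueError, TypeError) as exc:
            raise ConfigError(f"{name}: {exc}") from exc
    # sigma_th default: 30% of the configured yield strength unless explicit
    if "sigma_th" not in raw.get("corrosion", {}):
        blocks["corrosion"] = dataclasses.replace(
            blocks["corrosion"], sigma_th=0.30 * blocks["material"].yield_strength
        )
    try:
        cfg = SimulationConfig(
            group=raw.get("group", "C1"),
            dt=float(raw.get("dt", 0.1)),
            t_max=float(raw.get("t_max", 100.0)),
            snapshot_interval=float(raw.get("snapshot_interval", 0.0)),
            kappa=float(raw.get("kappa", 1.0)),
            rng_seed=raw.get("rng_seed"),
            material=blocks["material"],
            corrosion=blocks["corrosion"],
            fatigue=blocks["fatigue"],
            waveform=blocks["waveform"],
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc
    if cfg.corrosion.pitting_enabled and cfg.rng_seed is None and cfg.corrosion.rng_seed is None:
        raise ConfigError("rng_seed: required when corrosion.pitting_enabled is true")
    return cfg, dict(raw.get("mesh", {})), dict(raw.get("stress", {}))


# ---------------------------------------------------------------------------
# Abaqus INP subset
# ---------------------------------------------------------------------------

def read_inp(path: str | Path) -> HexMesh:
    """Read the supported INP subset: *NODE, *ELEMENT TYPE=C3D8(R),
    *ELSET[, ELSET=name].  Any other keyword block is skipped with a
    warning.  Node/element labels are mapped to contiguous 0-based indices
    in order of appearance."""
    nodes: dict[int, tuple[float, float, float]] = {}
    elems: dict[int, list[int]] = {}
    elsets: dict[str, list[int]] = {}
    mode = None
    current_set = None
    generate = False
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("**"):
            continue
        if line.startswith("*"):
            kw, _, rest = line.partition(",")
            kw = kw.strip().upper()
            opts = {}
            for item in rest.split(","):
                if "=" in item:
                    k, v = item.split("=", 1)
                    opts[k.strip().upper()] = v.strip()
                elif item.strip():
                    opts[item.strip().upper()] = True
            if kw == "*NODE":
                mode = "node"
            elif kw == "*ELEMENT":
                etype = str(opts.get("TYPE", "")).upper()
                if etype not in ("C3D8", "C3D8R"):
                    logger.warning("skipping unsupported element type %s", etype)
                    mode = None
                else:
                    mode = "element"
            elif kw == "*ELSET":
                mode = "elset"
                current_set = str(opts.get("ELSET", "unnamed"))
                generate = bool(opts.get("GENERATE", False))
                elsets.setdefault(current_set, [])
            else:
                logger.warning("ignoring unsupported keyword %s", kw)
                mode = None
            continue
        parts = [p for p in (s.strip() for s in line.split(",")) if p]
        if mode == "node":
            label = int(parts[0])
            xyz = tuple(float(v) for v in parts[1:4])
            nodes[label] = xyz
        elif mode == "element":
            label = int(parts[0])
            elems[label] = [int(v) for v in parts[1:9]]
        elif mode == "elset":
            vals = [int(v) for v in parts]
            if generate:
                start, stop = vals[0], vals[1]
                step_ = vals[2] if len(vals) > 2 else 1
                elsets[current_set].extend(range(start, stop + 1, step_))
            else:
                elsets[current_set].extend(vals)
    if not nodes or not elems:
        raise FormatError("INP file contains no supported *NODE/*ELEMENT data")
    node_order = sorted(nodes)
    node_map = {lab: i for i, lab in enumerate(node_order)}
    elem_order = sorted(elems)
    elem_map = {lab: i for i, lab in enumerate(elem_order)}
    coords = np.array([nodes[lab] for lab in node_order])
    connectivity = np.array([[node_map[n] for n in elems[lab]] for lab in elem_order], dtype=np.int64)
    labels = {
        name: np.array(sorted(elem_map[e] for e in members if e in elem_map), dtype=np.int64)
        for name, members in elsets.items()
        if members
    }
    return make_mesh(coords, connectivity, labels)


def write_inp(mesh: HexMesh, path: str | Path) -> None:
    """Write the mesh in the same INP subset (1-based labels, full double
    precision so a round trip is exact)."""
    lines = ["*NODE"]
    for i, (x, y, z) in enumerate(mesh.node_coords, start=1):
        lines.append(f"{i}, {float(x)!r}, {float(y)!r}, {float(z)!r}")
    lines.append("*ELEMENT, TYPE=C3D8R")
    for e, nodes in enumerate(mesh.elements, start=1):
        lines.append(f"{e}, " + ", ".join(str(int(n) + 1) for n in nodes))
    for name, members in mesh.element_set_labels.items():
        if len(members) == 0:
            continue
        lines.append(f"*ELSET, ELSET={name}")
        members = [str(int(m) + 1) for m in members]
        for i in range(0, len(members), 16):
            lines.append(", ".join(members[i:i + 16]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# VTU (ASCII XML UnstructuredGrid)
# ---------------------------------------------------------------------------

def write_vtu(mesh: HexMesh, path: str | Path, cell_data: dict[str, np.ndarray] | None = None) -> None:
    """Write the mesh and optional per-element scalar fields as an ASCII
    .vtu file (VTK UnstructuredGrid, hexahedron cell type 12) readable by
    ParaView and VTK-based tools."""
    n_pts, n_cells = mesh.n_nodes, mesh.n_elements
    out = []
    out.append('<?xml version="1.0"?>')
    out.append('<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">')
    out.append("<UnstructuredGrid>")
    out.append(f'<Piece NumberOfPoints="{n_pts}" NumberOfCells="{n_cells}">')
    out.append("<Points>")
    out.append('<DataArray type="Float64" NumberOfComponents="3" format="ascii">')
    out.append("\n".join(" ".join(repr(float(v)) for v in row) for row in mesh.node_coords))
    out.append("</DataArray></Points>")
    out.append("<Cells>")
    out.append('<DataArray type="Int64" Name="connectivity" format="ascii">')
    out.append("\n".join(" ".join(str(int(v)) for v in row) for row in mesh.elements))
    out.append("</DataArray>")
    out.append('<DataArray type="Int64" Name="offsets" format="ascii">')
    out.append(" ".join(str(8 * (i + 1)) for i in range(n_cells)))
    out.append("</DataArray>")
    out.append('<DataArray type="UInt8" Name="types" format="ascii">')
    out.append(" ".join("12" for _ in range(n_cells)))
    out.append("</DataArray></Cells>")
    out.append("<CellData>")
    for name, values in (cell_data or {}).items():
        values = np.asarray(values, dtype=float)
        if values.shape != (n_cells,):
            raise FormatError(f"cell field {name!r} must have one scalar per element")
        out.append(f'<DataArray type="Float64" Name="{name}" format="ascii">')
        out.append(" ".join(repr(float(v)) for v in values))
        out.append("</DataArray>")
    out.append("</CellData>")
    out.append("</Piece></UnstructuredGrid></VTKFile>")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Stress tables, time series, manifest
# ---------------------------------------------------------------------------

_TENSOR_COLS = ["sx", "sy", "sz", "txy", "tyz", "tzx"]


def read_stress_table(path: str | Path, n_elements: int, reference_pressure: float = 100.0) -> ResidualStressField:
    """Read a delimited per-element stress table (header required: either
    the six tensor columns sx..tzx or a single sigma_eq column, plus an
    optional leading ``element`` index column)."""
    df = pd.read_csv(path)
    cols = [c.strip() for c in df.columns]
    df.columns = cols
    if "element" in cols:
        df = df.sort_values("element").drop(columns=["element"])
    if all(c in df.columns for c in _TENSOR_COLS):
        table = df[_TENSOR_COLS].to_numpy(dtype=float)
    elif "sigma_eq" in df.columns:
        table = df["sigma_eq"].to_numpy(dtype=float)
    else:
        raise FormatError("stress table must provide sx..tzx columns or a sigma_eq column")
    return load_stress_field(table, n_elements, reference_pressure)


def write_stress_table(field: ResidualStressField, path: str | Path) -> None:
    df = pd.DataFrame(field.tensors, columns=_TENSOR_COLS)
    df.insert(0, "element", np.arange(field.n_elements))
    df.to_csv(path, index=False)


def write_mass_loss_csv(result: SimulationResult, path: str | Path) -> None:
    pd.DataFrame(
        {"time_h": result.time_grid, "mass_loss_fraction": result.mass_loss_fraction}
    ).to_csv(path, index=False)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(
    config: SimulationConfig,
    out_dir: str | Path,
    input_files: list[str | Path] = (),
    outputs: list[str] = (),
    extra: dict | None = None,
) -> Path:
    """Write a JSON manifest of the fully resolved configuration, input file
    checksums and output inventory — enough to reproduce the run exactly."""
    out_dir = Path(out_dir)
    manifest = {
        "package": "stentdamage",
        "version": _package_version(),
        "config": dataclasses.asdict(config),
        "rng_seed": config.rng_seed,
        "input_checksums": {str(p): _sha256(Path(p)) for p in input_files},
        "outputs": list(outputs),
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path


def _package_version() -> str:
    try:
        from importlib.metadata import version

        return version("stentdamage")
    except Exception:
        return "unknown"
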