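"""Hexahedral mesh construction, topology and fracture detection.

The simulator works on meshes of 8-node hexahedra (C3D8R-style).  Corrosion
acts on the *exposed* surface, which changes as elements are deleted, so the
mesh object carries a full face-adjacency table: an element face is either
shared with exactly one neighbouring element or free (domain boundary).  An
alive element is *exposed* as soon as at least one of its six faces is free or
borders a deleted element — this is how corrosion penetrates inward as the
outer layers are removed.

Structural fracture is detected as loss of face-connectivity of the alive
elements: the implant has broken once the surviving material no longer forms
a single connected piece.

Conventions: 0-based node/element indices, lengths in mm, volumes in mm^3.
Node ordering follows the Abaqus C3D8 convention (nodes 0-3 bottom face,
4-7 top face).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .errors import GeometryError

# Local faces of a C3D8 hexahedron (indices into the element's 8 nodes).
HEX_FACES = (
    (0, 1, 2, 3),
    (4, 5, 6, 7),
    (0, 1, 5, 4),
    (1, 2, 6, 5),
    (2, 3, 7, 6),
    (3, 0, 4, 7),
)

# Decomposition of a hexahedron into 6 tetrahedra sharing the 0-6 diagonal.
_HEX_TETS = (
    (0, 1, 2, 6),
    (0, 2, 3, 6),
    (0, 3, 7, 6),
    (0, 7, 4, 6),
    (0, 4, 5, 6),
    (0, 5, 1, 6),
)


@dataclass
class HexMesh:
    """An 8-node hexahedral volume mesh with face-adjacency topology.

    Attributes
    ----------
    node_coords : (n_nodes, 3) float array, mm
    elements : (n_elem, 8) int array
        Node indices per element, C3D8 ordering.
    face_adjacency : (n_elem, 6) int array
        For each element and local face, the index of the face-neighbour
        element, or -1 for a free (boundary) face.
    element_volume : (n_elem,) float array, mm^3
    element_set_labels : dict mapping set name to sorted int array
    """

    node_coords: np.ndarray
    elements: np.ndarray
    face_adjacency: np.ndarray
    element_volume: np.ndarray
    element_set_labels: dict[str, np.ndarray] = field(default_factory=dict)
    # Optional (n_elem, 6) bool mask: True marks a boundary face that is
    # sealed (coated / symmetry plane) and therefore never counts as a free
    # surface.  Faces opened by element deletion are never sealed.
    sealed_faces: np.ndarray | None = None

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.node_coords.shape[0]

    def characteristic_length(self, element: int) -> float:
        """Characteristic element length Le = volume^(1/3), in mm.

        Defined as the cube root of the element volume so that it reduces to
        the edge length for cubic elements and stays well-defined for
        distorted hexahedra.
        """
        if not 0 <= element < self.n_elements:
            raise ValueError(f"element index {element} out of range")
        return float(self.element_volume[element]) ** (1.0 / 3.0)

    def characteristic_lengths(self) -> np.ndarray:
        """Vectorised Le for all elements."""
        return np.cbrt(self.element_volume)

    def neighbor_matrix(self) -> np.ndarray:
        """Alias for the (n_elem, 6) adjacency table."""
        return self.face_adjacency


def _hex_volumes(node_coords: np.ndarray, elements: np.ndarray) -> np.ndarray:
    """Signed volumes via the 6-tetrahedron decomposition (exact for
    planar-faced hexahedra)."""
    vols = np.zeros(elements.shape[0])
    pts = node_coords[elements]  # (n, 8, 3)
    for a, b, c, d in _HEX_TETS:
        v0 = pts[:, b] - pts[:, a]
        v1 = pts[:, c] - pts[:, a]
        v2 = pts[:, d] - pts[:, a]
        vols += np.einsum("ij,ij->i", np.cross(v0, v1), v2) / 6.0
    return vols


def build_adjacency(elements: np.ndarray) -> np.ndarray:
    """Compute the (n_elem, 6) face-adjacency table by matching shared
    quad faces.  A face key is the sorted 4-tuple of its node indices;
    any face shared by more than two elements is a topology error."""
    n = elements.shape[0]
    adj = np.full((n, 6), -1, dtype=np.int64)
    face_map: dict[tuple[int, ...], tuple[int, int]] = {}
    for e in range(n):
        nodes = elements[e]
        for f, loc in enumerate(HEX_FACES):
            key = tuple(sorted(int(nodes[i]) for i in loc))
            if key in face_map:
                other_e, other_f = face_map.pop(key)
                if adj[e, f] != -1 or adj[other_e, other_f] != -1:
                    raise GeometryError("face shared by more than two elements")
                adj[e, f] = other_e
                adj[other_e, other_f] = e
            else:
                face_map[key] = (e, f)
    return adj


def _validate(mesh: HexMesh) -> HexMesh:
    els = mesh.elements
    if els.ndim != 2 or els.shape[1] != 8:
        raise GeometryError("elements must be (n, 8)")
    if np.any(els < 0) or np.any(els >= mesh.n_nodes):
        raise GeometryError("element node index out of range")
    for row in els:
        if len(set(int(i) for i in row)) != 8:
            raise GeometryError("element has repeated node indices")
    if np.any(mesh.element_volume <= 0):
        raise GeometryError("non-positive element volume (inverted or degenerate hexahedron)")
    return mesh


def make_mesh(
    node_coords: np.ndarray,
    elements: np.ndarray,
    element_set_labels: dict[str, np.ndarray] | None = None,
) -> HexMesh:
    """Assemble and validate a HexMesh from raw node/element arrays."""
    node_coords = np.asarray(node_coords, dtype=float)
    elements = np.asarray(elements, dtype=np.int64)
    mesh = HexMesh(
        node_coords=node_coords,
        elements=elements,
        face_adjacency=build_adjacency(elements),
        element_volume=_hex_volumes(node_coords, elements),
        element_set_labels={k: np.asarray(sorted(v), dtype=np.int64) for k, v in (element_set_labels or {}).items()},
    )
    return _validate(mesh)


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def build_slab_mesh(nx: int, ny: int, nz: int, element_size: float) -> HexMesh:
    """Structured slab of nx*ny*nz cubic elements with the given edge length (mm)."""
    if nx < 1 or ny < 1 or nz < 1:
        raise ValueError("slab dimensions must be >= 1")
    if element_size <= 0:
        raise ValueError("element_size must be positive")
    h = float(element_size)
    xs = np.arange(nx + 1) * h
    ys = np.arange(ny + 1) * h
    zs = np.arange(nz + 1) * h
    # node index (i, j, k) -> flat
    nnx, nny = nx + 1, ny + 1

    def nid(i, j, k):
        return (k * nny + j) * nnx + i

    coords = np.empty(((nx + 1) * (ny + 1) * (nz + 1), 3))
    for k in range(nz + 1):
        for j in range(ny + 1):
            for i in range(nx + 1):
                coords[nid(i, j, k)] = (xs[i], ys[j], zs[k])

    elements = []
    for k in range(nz):
        for j in range(ny):
            for i in range(nx):
                elements.append(
                    (
                        nid(i, j, k), nid(i + 1, j, k), nid(i + 1, j + 1, k), nid(i, j + 1, k),
                        nid(i, j, k + 1), nid(i + 1, j, k + 1), nid(i + 1, j + 1, k + 1), nid(i, j + 1, k + 1),
                    )
                )
    return make_mesh(coords, np.asarray(elements, dtype=np.int64))


def build_ring_stent_mesh(
    radius: float = 1.5,
    strut_width: float = 0.1,
    strut_thickness: float = 0.1,
    n_crowns: int = 6,
    elements_per_segment: int = 4,
) -> HexMesh:
    """Simplified single-ring stent: a closed zig-zag lattice of hexahedra
    wrapped around a cylinder.

    The centreline is a triangle wave on the cylinder surface with
    ``2 * n_crowns`` apexes alternating between z = +H/2 and z = -H/2
    (ring height H fixed at ``radius``).  Each straight segment between
    apexes is split into ``elements_per_segment`` hexahedra of cross-section
    ``strut_width`` x ``strut_thickness``, giving
    ``2 * n_crowns * elements_per_segment`` elements in a single closed loop.
    The two elements meeting at each apex are labelled ``"corolla"`` (the
    crown bend, where stress concentrates after deployment); the rest are
    labelled ``"strut"``.
    """
    if radius <= 0 or strut_width <= 0 or strut_thickness <= 0:
        raise ValueError("all ring dimensions must be positive")
    if n_crowns < 3:
        raise ValueError("n_crowns must be >= 3")
    if elements_per_segment < 1:
        raise ValueError("elements_per_segment must be >= 1")

    n_apex = 2 * n_crowns
    m = n_apex * elements_per_segment  # polyline vertices == elements (closed loop)
    height = radius

    # Centreline vertices on the cylinder: uniform angle, triangle-wave z.
    theta = 2.0 * np.pi * np.arange(m) / m
    apex_z = np.where(np.arange(n_apex) % 2 == 0, +height / 2.0, -height / 2.0)
    z = np.empty(m)
    for j in range(n_apex):
        z0, z1 = apex_z[j], apex_z[(j + 1) % n_apex]
        for s in range(elements_per_segment):
            z[j * elements_per_segment + s] = z0 + (z1 - z0) * s / elements_per_segment
    centre = np.column_stack([radius * np.cos(theta), radius * np.sin(theta), z])

    # Cross-section frame at each vertex: radial r_hat, tangent from the
    # neighbouring vertices, width direction w_hat = t_hat x r_hat.
    r_hat = np.column_stack([np.cos(theta), np.sin(theta), np.zeros(m)])
    tangent = centre[(np.arange(m) + 1) % m] - centre[(np.arange(m) - 1) % m]
    tangent /= np.linalg.norm(tangent, axis=1, keepdims=True)
    w_hat = np.cross(tangent, r_hat)
    w_hat /= np.linalg.norm(w_hat, axis=1, keepdims=True)

    hr = 0.5 * strut_thickness * r_hat
    hw = 0.5 * strut_width * w_hat
    # 4 corner nodes per cross-section, ordered so that consecutive sections
    # stack into positively oriented hexahedra.
    corners = np.stack(
        [centre - hr - hw, centre + hr - hw, centre + hr + hw, centre - hr + hw],
        axis=1,
    )  # (m, 4, 3)
    coords = corners.reshape(-1, 3)

    def sec(i, c):
        return (i % m) * 4 + c

    elements = np.array(
        [[sec(i, 0), sec(i, 1), sec(i, 2), sec(i, 3),
          sec(i + 1, 0), sec(i + 1, 1), sec(i + 1, 2), sec(i + 1, 3)] for i in range(m)],
        dtype=np.int64,
    )

    # Crude overlap guard: cross-section must be smaller than vertex spacing.
    spacing = np.linalg.norm(centre[1] - centre[0])
    if strut_width > 2.0 * np.pi * radius / m * 4 and strut_width > spacing * 2:
        raise GeometryError("strut_width too large for the requested tiling (self-intersection)")

    apex_vertices = np.arange(n_apex) * elements_per_segment
    corolla = sorted({int(a % m) for a in apex_vertices} | {int((a - 1) % m) for a in apex_vertices})
    strut = sorted(set(range(m)) - set(corolla))
    try:
        mesh = make_mesh(coords, elements, {"corolla": corolla, "strut": strut})
    except GeometryError as exc:
        raise GeometryError(f"ring parameters produce invalid geometry: {exc}") from exc
    return mesh


def ring_element_count(n_crowns: int, elements_per_segment: int) -> int:
    """Closed-form element count of :func:`build_ring_stent_mesh`."""
    return 2 * n_crowns * elements_per_segment


# ---------------------------------------------------------------------------
# Topology queries
# ---------------------------------------------------------------------------

def exposed_elements(mesh: HexMesh, alive: np.ndarray) -> set[int]:
    """Alive elements with at least one free face.

    A face is free if it lies on the domain boundary or if the neighbour
    across it has been deleted; deleted elements are never exposed.
    """
    alive = np.asarray(alive, dtype=bool)
    return set(np.flatnonzero(exposure_mask(mesh, alive)).tolist())


def exposure_mask(mesh: HexMesh, alive: np.ndarray) -> np.ndarray:
    """Boolean exposure mask over all elements (vectorised form of
    :func:`exposed_elements`).

    A face is free if it is an unsealed boundary face or faces a deleted
    neighbour; an alive element is exposed iff it has at least one free face.
    """
    adj = mesh.face_adjacency
    alive = np.asarray(alive, dtype=bool)
    valid = adj >= 0
    dead_neighbor = np.zeros(adj.shape, dtype=bool)
    dead_neighbor[valid] = ~alive[adj[valid]]
    boundary = ~valid
    if mesh.sealed_faces is not None:
        boundary = boundary & ~np.asarray(mesh.sealed_faces, dtype=bool)
    free = boundary | dead_neighbor
    return alive & free.any(axis=1)


def is_fractured(mesh: HexMesh, alive: np.ndarray) -> bool:
    """True once the alive elements no longer form a single face-connected
    component (the implant has been severed).  All-dead counts as fractured;
    a single surviving element does not."""
    alive = np.asarray(alive, dtype=bool)
    idx = np.flatnonzero(alive)
    if idx.size == 0:
        return True
    if idx.size == 1:
        return False
    remap = -np.ones(mesh.n_elements, dtype=np.int64)
    remap[idx] = np.arange(idx.size)
    adj = mesh.face_adjacency[idx]
    rows, cols = [], []
    for f in range(6):
        nb = adj[:, f]
        ok = (nb >= 0) & alive[np.clip(nb, 0, None)]
        src = np.arange(idx.size)[ok]
        dst = remap[nb[ok]]
        rows.append(src)
        cols.append(dst)
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    graph = coo_matrix((np.ones(rows.size), (rows, cols)), shape=(idx.size, idx.size))
    n_comp, _ = connected_components(graph, directed=False)
    return bool(n_comp > 1)


def characteristic_length(mesh: HexMesh, element: int) -> float:
    """Module-level alias of :meth:`HexMesh.characteristic_length`."""
    return mesh.characteristic_length(element)


def face_unit_normals(mesh: HexMesh) -> np.ndarray:
    """Outward unit normal of every element face, shape (n_elem, 6, 3)."""
    pts = mesh.node_coords[mesh.elements]  # (n, 8, 3)
    centres = pts.mean(axis=1)
    normals = np.zeros((mesh.n_elements, 6, 3))
    for f, (a, b, c, d) in enumerate(HEX_FACES):
        nrm = np.cross(pts[:, c] - pts[:, a], pts[:, d] - pts[:, b])
        nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
        face_centre = (pts[:, a] + pts[:, b] + pts[:, c] + pts[:, d]) / 4.0
        sign = np.sign(np.einsum("ij,ij->i", nrm, face_centre - centres))
        normals[:, f] = nrm * sign[:, None]
    return normals


def seal_all_but_axis_ends(mesh: HexMesh, axis: int = 0, ends: tuple[str, ...] = ("min", "max")) -> np.ndarray:
    """Sealed-face mask exposing only the boundary faces whose outward normal
    points along the requested end(s) of the given axis.

    Useful for 1-D corrosion-front studies: sealing the lateral faces of an
    nx x 1 x 1 column makes corrosion enter only through the chosen end(s),
    so the front peels one layer per Le / (delta_U * k_U) hours.  Assign the
    result to ``mesh.sealed_faces``.
    """
    normals = face_unit_normals(mesh)
    boundary = mesh.face_adjacency < 0
    comp = normals[:, :, axis]
    keep = np.zeros_like(boundary)
    if "max" in ends:
        keep |= comp > 0.9
    if "min" in ends:
        keep |= comp < -0.9
    return boundary & ~keep
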