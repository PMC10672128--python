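import dataclasses

import numpy as np
import pytest
from hypothesis import settings

import stentdamage as sd

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def slab3() -> sd.HexMesh:
    return sd.build_slab_mesh(3, 1, 1, 0.1)


@pytest.fixture(scope="session")
def slab333() -> sd.HexMesh:
    return sd.build_slab_mesh(3, 3, 3, 0.1)


@pytest.fixture(scope="session")
def ring() -> sd.HexMesh:
    return sd.build_ring_stent_mesh(radius=1.5, strut_width=0.1, strut_thickness=0.1,
                                    n_crowns=6, elements_per_segment=4)


@pytest.fixture
def no_pitting() -> sd.CorrosionParams:
    return dataclasses.replace(sd.CorrosionParams(), pitting_enabled=False)


def brute_force_exposed(mesh: sd.HexMesh, alive: np.ndarray) -> set[int]:
    """Independent exposure oracle: all-pairs face matching on node sets."""
    from stentdamage.mesh import HEX_FACES

    faces = {}
    for e in range(mesh.n_elements):
        if not alive[e]:
            continue
        for loc in HEX_FACES:
            key = frozenset(int(mesh.elements[e][i]) for i in loc)
            faces.setdefault(key, []).append(e)
    exposed = set()
    for e in range(mesh.n_elements):
        if not alive[e]:
            continue
        sealed = mesh.sealed_faces
        for f, loc in enumerate(HEX_FACES):
            key = frozenset(int(mesh.elements[e][i]) for i in loc)
            if len(faces[key]) == 1:
                if sealed is not None and mesh.face_adjacency[e, f] < 0 and sealed[e, f]:
                    continue  # coated boundary face
                exposed.add(e)
                break
    return exposed


def brute_force_fractured(mesh: sd.HexMesh, alive: np.ndarray) -> bool:
    """Independent fracture oracle: BFS connected components over alive elements."""
    idx = [e for e in range(mesh.n_elements) if alive[e]]
    if not idx:
        return True
    seen = {idx[0]}
    stack = [idx[0]]
    while stack:
        e = stack.pop()
        for nb in mesh.face_adjacency[e]:
            if nb >= 0 and alive[nb] and nb not in seen:
                seen.add(int(nb))
                stack.append(int(nb))
    return len(seen) != len(idx)
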