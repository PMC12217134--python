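"""Shared fixtures: phantoms are generated programmatically (no stored
binary fixtures), session-scoped where construction is not trivial."""

from __future__ import annotations

import numpy as np
import pytest
import trimesh

import rodentmorph as rm
from rodentmorph.types import TriangleMesh


@pytest.fixture(scope="session")
def cube_mesh() -> TriangleMesh:
    """Unit cube centered at the origin (8 vertices, 12 triangles)."""
    return TriangleMesh.from_trimesh(trimesh.creation.box(extents=[1.0, 1.0, 1.0]))


@pytest.fixture(scope="session")
def tube_phantom():
    """Rat-scale constant-radius tube (r = 0.3 mm, L = 2 mm) + manifest."""
    spec = rm.LigamentPhantomSpec(
        length=2.0,
        radius_profile={"kind": "constant", "r0": 0.3},
        cross_section={"kind": "circle", "r": 0.3},
        seed=1,
    )
    return rm.make_ligament_phantom(spec)


@pytest.fixture(scope="session")
def crescent_phantom():
    """Tube with a non-convex crescent cross-section + manifest."""
    spec = rm.LigamentPhantomSpec(
        length=2.0,
        cross_section={
            "kind": "crescent",
            "r_outer": 0.3,
            "r_inner": 0.15,
            "offset": 0.25,
        },
        seed=4,
    )
    return rm.make_ligament_phantom(spec)


@pytest.fixture(scope="session")
def meniscus_phantom():
    """Lateral C-shape with horns 1.2x the central cross-section."""
    spec = rm.MeniscusPhantomSpec(horn_scale=1.2, side="lateral", seed=7)
    return rm.make_meniscus_phantom(spec)


@pytest.fixture(scope="session")
def sphere_mesh() -> TriangleMesh:
    """Icosphere of radius 0.5 mm (volume 4/3 pi 0.125)."""
    return TriangleMesh.from_trimesh(trimesh.creation.icosphere(subdivisions=4, radius=0.5))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)
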