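"""Synthetic phantoms and simulated measurement tables with analytic
ground truth.

No imaging data ships with the package, so every pipeline stage is
exercised on generated stand-ins: tube-like ligament surfaces with a
known radius profile and cross-section, C-shaped swept menisci with known
regional widths/heights, single-slice footprint masks, and paired
rater/method tables with known variance components. Each generator is a
pure function of its spec and seed, and returns the analytic values a
correct pipeline should recover alongside the artifact itself.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point, Polygon

from .types import LabelVolume, TriangleMesh

__all__ = [
    "LigamentPhantomSpec",
    "MeniscusPhantomSpec",
    "GroundTruthManifest",
    "make_ligament_phantom",
    "make_meniscus_phantom",
    "make_footprint_mask",
    "make_agreement_pairs",
    "make_cohort_table",
]

# sub-stream codes so each generator draws from an independent stream
_STREAM = {"ligament": 11, "meniscus": 23, "footprint": 37, "agreement": 53, "cohort": 71}


def _rng(op: str, seed: int) -> np.random.Generator:
    return np.random.default_rng([_STREAM[op], int(seed)])


@dataclass
class GroundTruthManifest:
    """Analytic targets a correct pipeline should reproduce, plus the
    generator parameters and seed that make the phantom reproducible."""

    kind: str
    params: Dict
    seed: int
    values: Dict

    def to_json(self, path) -> None:
        def _clean(obj):
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            if isinstance(obj, dict):
                return {k: _clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_clean(v) for v in obj]
            return obj

        with open(path, "w") as fh:
            json.dump(_clean(asdict(self)), fh, indent=2)


# ---------------------------------------------------------------------------
# cross-section boundaries


def _ellipse_boundary(a: float, b: float, n: int) -> Tuple[np.ndarray, float, float]:
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = np.column_stack([a * np.cos(th), b * np.sin(th)])
    area = np.pi * a * b
    # Ramanujan perimeter approximation
    h = ((a - b) / (a + b)) ** 2
    perim = np.pi * (a + b) * (1 + 3 * h / (10 + np.sqrt(4 - 3 * h)))
    return pts, area, perim


def _lens_area(R: float, r: float, d: float) -> float:
    """Area of intersection of two circles (radii R, r, center distance d)."""
    if d >= R + r:
        return 0.0
    if d <= abs(R - r):
        return np.pi * min(R, r) ** 2
    t1 = R**2 * np.arccos((d**2 + R**2 - r**2) / (2 * d * R))
    t2 = r**2 * np.arccos((d**2 + r**2 - R**2) / (2 * d * r))
    t3 = 0.5 * np.sqrt((-d + r + R) * (d + r - R) * (d - r + R) * (d + r + R))
    return t1 + t2 - t3


def _crescent_boundary(
    r_outer: float, r_inner: float, offset: float, n: int
) -> Tuple[np.ndarray, float, float]:
    """Crescent (lune): outer disc minus an offset inner disc that pokes out."""
    if not (abs(r_outer - r_inner) < offset < r_outer + r_inner):
        raise ValueError(
            "crescent requires the inner circle to overlap the outer boundary: "
            "|r_outer - r_inner| < offset < r_outer + r_inner"
        )
    outer = Point(0, 0).buffer(r_outer, quad_segs=max(64, n))
    inner = Point(offset, 0).buffer(r_inner, quad_segs=max(64, n))
    lune = outer.difference(inner)
    ring = lune.exterior
    dist = np.linspace(0, ring.length, n, endpoint=False)
    pts = np.array([ring.interpolate(t).coords[0] for t in dist])
    area = np.pi * r_outer**2 - _lens_area(r_outer, r_inner, offset)
    return pts, area, ring.length


def _base_boundary(cross_section: Dict, n: int) -> Tuple[np.ndarray, float, float]:
    kind = cross_section["kind"]
    if kind == "circle":
        r = cross_section["r"]
        return _ellipse_boundary(r, r, n)
    if kind == "ellipse":
        return _ellipse_boundary(cross_section["a"], cross_section["b"], n)
    if kind == "crescent":
        return _crescent_boundary(
            cross_section["r_outer"],
            cross_section["r_inner"],
            cross_section["offset"],
            n,
        )
    raise ValueError(f"unknown cross_section kind {kind!r}")


# ---------------------------------------------------------------------------
# ligament tube phantom


@dataclass
class LigamentPhantomSpec:
    """Tube-like ligament phantom: a cross-section swept along a straight
    axis with a radius profile (constant, linear taper, or flared ends
    mimicking bony insertions).

    vertex_density is surface points per mm^2; the default gives well over
    100 points per 0.05 mm slab at rat/mouse ligament scale.
    """

    length: float = 2.0
    radius_profile: Dict = field(default_factory=lambda: {"kind": "constant", "r0": 0.3})
    cross_section: Dict = field(default_factory=lambda: {"kind": "circle", "r": 0.3})
    axis_direction: Tuple[float, float, float] = (0.0, 0.0, 1.0)
    vertex_density: float = 2000.0
    jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("length must be positive")
        if self.vertex_density <= 0:
            raise ValueError("vertex_density must be positive")
        kind = self.radius_profile.get("kind")
        if kind not in ("constant", "linear", "flared"):
            raise ValueError(f"unknown radius_profile kind {kind!r}")
        radii = [v for k, v in self.radius_profile.items() if k.startswith("r")]
        if any(r <= 0 for r in radii):
            raise ValueError("all profile radii must be positive")
        if kind == "flared":
            ff = self.radius_profile.get("flare_fraction", 0.25)
            if not (0 < ff < 0.5):
                raise ValueError("flare_fraction must lie in (0, 0.5)")


def _radius_scale(profile: Dict, t: np.ndarray) -> np.ndarray:
    """Relative radius r(t)/r(mid) for normalized position t in [0, 1]."""
    kind = profile["kind"]
    if kind == "constant":
        return np.ones_like(t)
    if kind == "linear":
        r0, r1 = profile["r0"], profile["r1"]
        r_mid = 0.5 * (r0 + r1)
        return (r0 + (r1 - r0) * t) / r_mid
    # flared: r_mid in the middle, ramping to r_end over the end fractions
    r_mid, r_end = profile["r_mid"], profile["r_end"]
    ff = profile.get("flare_fraction", 0.25)
    scale = np.ones_like(t)
    lo = t < ff
    hi = t > 1 - ff
    scale[lo] = (r_end + (r_mid - r_end) * (t[lo] / ff)) / r_mid
    scale[hi] = (r_end + (r_mid - r_end) * ((1 - t[hi]) / ff)) / r_mid
    return scale


def _rotation_to(axis: np.ndarray) -> np.ndarray:
    """Right-handed rotation taking +z onto the given unit axis."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, axis)
    c = float(np.dot(z, axis))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1 + c)


def _cap_faces(boundary2d: np.ndarray, ring_offset: int, flip: bool) -> np.ndarray:
    """Triangulate a cap over one boundary ring, reusing ring vertices only."""
    poly = Polygon(boundary2d)
    tris = shapely.constrained_delaunay_triangles(poly)
    # map triangle corners back to ring vertex indices by coordinate lookup
    lookup = {tuple(np.round(p, 12)): i for i, p in enumerate(boundary2d)}
    faces = []
    for g in tris.geoms:
        coords = np.asarray(g.exterior.coords)[:-1]
        idx = [lookup[tuple(np.round(c, 12))] for c in coords]
        faces.append(idx[::-1] if flip else idx)
    return np.asarray(faces, dtype=np.int64) + ring_offset


def _loft(rings: np.ndarray, cap_lo: np.ndarray, cap_hi: np.ndarray) -> TriangleMesh:
    """Stitch (n_z, n_theta, 3) rings into a closed tube with the given
    cap boundaries (2D, for triangulation)."""
    n_z, n_t, _ = rings.shape
    vertices = rings.reshape(-1, 3)
    faces = []
    for i in range(n_z - 1):
        base = i * n_t
        for j in range(n_t):
            a = base + j
            b = base + (j + 1) % n_t
            c = a + n_t
            d = b + n_t
            faces.append([a, b, d])
            faces.append([a, d, c])
    side = np.asarray(faces, dtype=np.int64)
    lo = _cap_faces(cap_lo, 0, flip=True)
    hi = _cap_faces(cap_hi, (n_z - 1) * n_t, flip=False)
    import trimesh

    tm = trimesh.Trimesh(
        vertices=vertices, faces=np.vstack([side, lo, hi]), process=False
    )
    trimesh.repair.fix_normals(tm)
    return TriangleMesh.from_trimesh(tm)


def make_ligament_phantom(
    spec: LigamentPhantomSpec,
) -> Tuple[TriangleMesh, GroundTruthManifest]:
    """Generate a watertight ligament tube and its analytic CSA profile.

    The manifest carries CSA(z) on a dense grid, the analytic midsubstance
    CSA (mean of CSA over the middle 50% of the length), and the generator
    parameters. With ``jitter_sd = 0`` (default) the surface is an exact
    parametric lattice; jitter perturbs vertices to stress tolerances.
    """
    L = spec.length
    h = 1.0 / np.sqrt(spec.vertex_density)
    base, base_area, perim = _base_boundary(spec.cross_section, 8)
    n_theta = max(32, int(round(perim / h)))
    n_z = max(9, int(round(L / h)) + 1)
    base, base_area, perim = _base_boundary(spec.cross_section, n_theta)

    t = np.linspace(0.0, 1.0, n_z)
    scale = _radius_scale(spec.radius_profile, t)
    rings = np.empty((n_z, n_theta, 3))
    rings[:, :, 0] = scale[:, None] * base[:, 0]
    rings[:, :, 1] = scale[:, None] * base[:, 1]
    rings[:, :, 2] = (t * L)[:, None]

    mesh = _loft(rings, base * scale[0], base * scale[-1])

    rot = _rotation_to(np.asarray(spec.axis_direction, dtype=float))
    verts = mesh.vertices @ rot.T
    if spec.jitter_sd > 0:
        rng = _rng("ligament", spec.seed)
        verts = verts + rng.normal(0.0, spec.jitter_sd, size=verts.shape)
    mesh = TriangleMesh(vertices=verts, faces=mesh.faces, name="other")

    t_dense = np.linspace(0.0, 1.0, 2001)
    s_dense = _radius_scale(spec.radius_profile, t_dense)
    csa_dense = base_area * s_dense**2
    mid = (t_dense >= 0.25) & (t_dense <= 0.75)
    manifest = GroundTruthManifest(
        kind="ligament_phantom",
        params=asdict(spec),
        seed=spec.seed,
        values={
            "base_csa_mm2": float(base_area),
            "z_mm": t_dense * L,
            "csa_by_z_mm2": csa_dense,
            "midsubstance_csa_mm2": float(csa_dense[mid].mean()),
            "length_mm": float(L),
        },
    )
    return mesh, manifest


# ---------------------------------------------------------------------------
# meniscus phantom


@dataclass
class MeniscusPhantomSpec:
    """C-shaped wedge meniscus phantom: an elliptical cross-section
    (width 2a medial-lateral/radial, height 2b proximal-distal) swept
    along a circular arc, with the end fifths of the arc (the horns)
    scaled by ``horn_scale``."""

    ring_radius: float = 2.0
    sweep_degrees: float = 180.0
    section_width: float = 1.0  # 2a
    section_height: float = 0.8  # 2b
    horn_scale: float = 1.0
    side: str = "lateral"
    vertex_density: float = 2000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.section_width <= 0 or self.section_height <= 0:
            raise ValueError("section dimensions must be positive")
        if self.ring_radius <= self.section_width / 2:
            raise ValueError("ring_radius must exceed the section half-width")
        if not (90 < self.sweep_degrees < 360):
            raise ValueError("sweep_degrees must lie in (90, 360)")
        if self.horn_scale <= 0:
            raise ValueError("horn_scale must be positive")
        if self.side not in ("medial", "lateral"):
            raise ValueError("side must be 'medial' or 'lateral'")


def _horn_profile(u: np.ndarray, horn_scale: float, blend: float = 0.05) -> np.ndarray:
    """Cross-section scale along the normalized arc position u in [0, 1]:
    horn_scale on the end fifths, 1 centrally, smoothstep blend between."""
    def smoothstep(x):
        x = np.clip(x, 0.0, 1.0)
        return x * x * (3 - 2 * x)

    lo = smoothstep((0.2 - u) / blend + 0.5)   # 1 near the start (horn)
    hi = smoothstep((u - 0.8) / blend + 0.5)   # 1 near the end (horn)
    w = np.maximum(lo, hi)
    return 1.0 + (horn_scale - 1.0) * w


def make_meniscus_phantom(
    spec: MeniscusPhantomSpec,
) -> Tuple[TriangleMesh, GroundTruthManifest]:
    """Generate a C-shaped meniscus and its analytic regional geometry.

    The arc lies in the x-y plane with its circumferential apex on +x for
    a lateral meniscus (-x for medial) and the two free ends (anterior
    horn at +y, posterior horn at -y). The manifest carries the analytic
    central and horn widths/heights and the apex/horn-end coordinates for
    region-selection tests.
    """
    a = spec.section_width / 2
    b = spec.section_height / 2
    R = spec.ring_radius
    half = np.deg2rad(spec.sweep_degrees) / 2

    h = 1.0 / np.sqrt(spec.vertex_density)
    ell, _, perim = _ellipse_boundary(a, b, 8)
    n_theta = max(32, int(round(perim / h)))
    arc_len = R * 2 * half
    n_phi = max(33, int(round(arc_len / h)) + 1)
    ell, _, _ = _ellipse_boundary(a, b, n_theta)

    phi = np.linspace(-half, half, n_phi)
    u = (phi + half) / (2 * half)
    s = _horn_profile(u, spec.horn_scale)

    rings = np.empty((n_phi, n_theta, 3))
    cos_p, sin_p = np.cos(phi), np.sin(phi)
    # cross-section spans the radial direction (width) and z (height)
    radial = s[:, None] * ell[:, 0][None, :]
    rings[:, :, 0] = (R + radial) * cos_p[:, None]
    rings[:, :, 1] = (R + radial) * sin_p[:, None]
    rings[:, :, 2] = s[:, None] * ell[:, 1][None, :]

    mesh = _loft(rings, ell * s[0], ell * s[-1])
    verts = mesh.vertices
    if spec.side == "medial":
        verts = verts * np.array([-1.0, 1.0, 1.0])
        import trimesh

        tm = trimesh.Trimesh(vertices=verts, faces=mesh.faces, process=False)
        trimesh.repair.fix_normals(tm)
        mesh = TriangleMesh.from_trimesh(tm)
    else:
        mesh = TriangleMesh(vertices=verts, faces=mesh.faces)
    mesh.name = f"{spec.side}_meniscus"

    sign = 1.0 if spec.side == "lateral" else -1.0
    manifest = GroundTruthManifest(
        kind="meniscus_phantom",
        params=asdict(spec),
        seed=spec.seed,
        values={
            "central_width_mm": 2 * a,
            "central_height_mm": 2 * b,
            "horn_width_mm": spec.horn_scale * 2 * a,
            "horn_height_mm": spec.horn_scale * 2 * b,
            "apex_xyz": [sign * (R + a), 0.0, 0.0],
            "anterior_horn_end_xyz": [
                sign * R * np.cos(half),
                R * np.sin(half),
                0.0,
            ],
            "posterior_horn_end_xyz": [
                sign * R * np.cos(half),
                -R * np.sin(half),
                0.0,
            ],
        },
    )
    return mesh, manifest


# ---------------------------------------------------------------------------
# footprint masks


def make_footprint_mask(
    shape: Dict,
    voxel_size: float,
    seed: int = 0,
) -> Tuple[LabelVolume, GroundTruthManifest]:
    """Single-axial-slice tibial footprint mask.

    ``shape`` is ``{"kind": "ellipse", "a": ..., "b": ...}`` (semi-axes,
    mm; a voxel is set iff its center lies inside, so the analytic area
    pi*a*b is also recorded) or ``{"kind": "blob", "r0": ...}`` (a seeded
    freeform outline built from random low-order harmonics on a circle).
    """
    if voxel_size <= 0:
        raise ValueError("voxel_size must be positive")
    kind = shape["kind"]
    if kind == "ellipse":
        a, b = shape["a"], shape["b"]
        radius = lambda th: (a * b) / np.sqrt(
            (b * np.cos(th)) ** 2 + (a * np.sin(th)) ** 2
        )
        extent = max(a, b)
        analytic = np.pi * a * b
    elif kind == "blob":
        r0 = shape["r0"]
        rng = _rng("footprint", seed)
        amps = rng.uniform(-0.1, 0.1, size=4) * r0
        phases = rng.uniform(0, 2 * np.pi, size=4)

        def radius(th):
            r = np.full_like(np.asarray(th, dtype=float), r0)
            for k, (amp, ph) in enumerate(zip(amps, phases), start=2):
                r = r + amp * np.cos(k * th + ph)
            return r

        extent = r0 * 1.5
        analytic = None
    else:
        raise ValueError(f"unknown footprint shape {kind!r}")

    n = int(np.ceil(2 * (extent + 2 * voxel_size) / voxel_size))
    centers = (np.arange(n) - (n - 1) / 2) * voxel_size
    xg, yg = np.meshgrid(centers, centers, indexing="ij")
    theta = np.arctan2(yg, xg)
    inside = np.hypot(xg, yg) < radius(theta)
    mask = np.zeros((n, n, 3), dtype=np.uint8)
    mask[:, :, 1] = inside
    vol = LabelVolume(mask=mask, voxel_size=voxel_size)
    values = {
        "n_voxels": int(inside.sum()),
        "area_mm2": float(inside.sum() * voxel_size**2),
    }
    if analytic is not None:
        values["analytic_area_mm2"] = float(analytic)
    manifest = GroundTruthManifest(
        kind="footprint_mask",
        params={"shape": shape, "voxel_size": voxel_size},
        seed=seed,
        values=values,
    )
    return vol, manifest


# ---------------------------------------------------------------------------
# measurement tables


def make_agreement_pairs(
    n: int,
    subject_sd: float,
    rater_bias: float = 0.0,
    error_sd: float = 1.0,
    seed: int = 0,
    mu: float = 10.0,
) -> Tuple[pd.DataFrame, GroundTruthManifest]:
    """Paired two-rater (or two-method) measurements with known variance
    components.

    Subjects are Normal(mu, subject_sd^2); rater 1 reads the subject with
    Normal(0, error_sd^2) noise; rater 2 additionally carries the fixed
    offset ``rater_bias``. The manifest records the analytic absolute-
    agreement target ICC(A,1) = s^2 / (s^2 + bias^2/2 + e^2) and the
    Bland-Altman bias target mean(rater1 - rater2) = -rater_bias.
    """
    if n < 3:
        raise ValueError("need n >= 3 subjects")
    if subject_sd < 0 or error_sd < 0:
        raise ValueError("standard deviations must be nonnegative")
    rng = _rng("agreement", seed)
    subjects = mu + rng.normal(0.0, subject_sd, size=n)
    r1 = subjects + rng.normal(0.0, error_sd, size=n)
    r2 = subjects + rater_bias + rng.normal(0.0, error_sd, size=n)
    table = pd.DataFrame(
        {"subject": np.arange(1, n + 1), "rater1": r1, "rater2": r2}
    )
    s2, e2 = subject_sd**2, error_sd**2
    denom = s2 + rater_bias**2 / 2 + e2
    manifest = GroundTruthManifest(
        kind="agreement_pairs",
        params={
            "n": n,
            "subject_sd": subject_sd,
            "rater_bias": rater_bias,
            "error_sd": error_sd,
            "mu": mu,
        },
        seed=seed,
        values={
            "icc_target": float(s2 / denom) if denom > 0 else 1.0,
            "bias_target": float(-rater_bias),
            "diff_convention": "rater1 - rater2",
        },
    )
    return table, manifest


def make_cohort_table(
    effects,
    noise_sd: float,
    n_per_group: int,
    seed: int = 0,
) -> Tuple[pd.DataFrame, GroundTruthManifest]:
    """Tidy per-specimen cohort table around supplied group means.

    ``effects`` is a list of dicts, each holding label columns (species,
    tissue, region, side, ...) plus ``mean`` and optionally ``sd`` (which
    overrides ``noise_sd`` for that group). Values are drawn Normal(mean,
    sd); with zero noise, group values equal the supplied means exactly.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    rng = _rng("cohort", seed)
    rows = []
    for group in effects:
        labels = {k: v for k, v in group.items() if k not in ("mean", "sd")}
        sd = group.get("sd", noise_sd)
        draws = group["mean"] + rng.normal(0.0, sd, size=n_per_group)
        for i, v in enumerate(draws, start=1):
            rows.append({"specimen": i, **labels, "value": float(v)})
    table = pd.DataFrame(rows)
    manifest = GroundTruthManifest(
        kind="cohort_table",
        params={"noise_sd": noise_sd, "n_per_group": n_per_group},
        seed=seed,
        values={"true_means": [dict(g) for g in effects]},
    )
    return table, manifest
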