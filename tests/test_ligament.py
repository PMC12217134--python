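"""Ligament alignment, slicing, midsubstance CSA, and normalization."""

import numpy as np
import pytest

import rodentmorph as rm
from rodentmorph.ligament import midsubstance_csa, normalize_csa, round_half_away
from rodentmorph.types import (
    CsaProfile,
    DegenerateAxisError,
    MorphometryConfig,
    PointCloud,
    SliceSection,
    TriangleMesh,
)


def _cylinder_cloud(radius=0.3, length=2.0, axis=(0, 0, 1), n=4000, seed=0):
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0, 2 * np.pi, n)
    z = rng.uniform(0, length, n)
    pts = np.column_stack([radius * np.cos(theta), radius * np.sin(theta), z])
    axis = np.asarray(axis, dtype=float)
    axis /= np.linalg.norm(axis)
    from rodentmorph.synthetic import _rotation_to

    return PointCloud(points=pts @ _rotation_to(axis).T, source="ACL")


def _random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _pipeline_csa(mesh: TriangleMesh, cfg: MorphometryConfig) -> float:
    cloud = rm.mesh_to_pointcloud(mesh)
    aligned, _ = rm.align_longitudinal(cloud)
    return rm.slice_profile(aligned, cfg).midsubstance_csa


class TestAlignment:
    def test_tilted_cylinder_extents(self):
        cloud = _cylinder_cloud(axis=(1, 1, 1))
        aligned, frame = rm.align_longitudinal(cloud)
        ext = np.ptp(aligned.points, axis=0)
        assert ext[2] == pytest.approx(2.0, abs=0.02)
        assert ext[0] == pytest.approx(0.6, abs=0.02)
        assert ext[1] == pytest.approx(0.6, abs=0.02)
        # frame invariant: rotation is right-handed orthonormal
        assert np.allclose(frame.rotation @ frame.rotation.T, np.eye(3), atol=1e-10)
        assert np.linalg.det(frame.rotation) == pytest.approx(1.0)

    def test_z_cylinder_keeps_axis(self):
        cloud = _cylinder_cloud(axis=(0, 0, 1))
        _, frame = rm.align_longitudinal(cloud)
        # longitudinal row maps onto +/- z
        assert abs(frame.rotation[2, 2]) == pytest.approx(1.0, abs=1e-3)

    def test_sphere_cloud_degenerate(self, rng):
        pts = rng.normal(size=(2000, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        with pytest.raises(DegenerateAxisError):
            rm.align_longitudinal(PointCloud(points=pts))

    def test_deterministic_sign(self):
        cloud = _cylinder_cloud(axis=(1, 1, 1), seed=3)
        a1, f1 = rm.align_longitudinal(cloud)
        a2, f2 = rm.align_longitudinal(cloud)
        np.testing.assert_array_equal(f1.rotation, f2.rotation)
        np.testing.assert_array_equal(a1.points, a2.points)


class TestSliceProfile:
    def test_cylinder_sections(self, tube_phantom):
        mesh, _ = tube_phantom
        aligned, _ = rm.align_longitudinal(rm.mesh_to_pointcloud(mesh))
        profile = rm.slice_profile(aligned, MorphometryConfig(species="rat"))
        assert profile.n_sections == 20
        np.testing.assert_allclose(profile.areas, np.pi * 0.09, rtol=0.02)

    def test_cone_monotone(self):
        spec = rm.LigamentPhantomSpec(
            radius_profile={"kind": "linear", "r0": 0.3, "r1": 0.12},
            cross_section={"kind": "circle", "r": 0.21},
            seed=2,
        )
        mesh, manifest = rm.make_ligament_phantom(spec)
        cloud = rm.mesh_to_pointcloud(mesh)
        aligned, _ = rm.align_longitudinal(cloud)
        profile = rm.slice_profile(aligned, MorphometryConfig(species="rat"))
        # areas shrink monotonically toward the narrow end (the data-driven
        # z-sign may point either way), tolerating 2% slice noise
        areas = profile.areas
        if areas[0] < areas[-1]:
            areas = areas[::-1]
        assert np.all(areas[1:] < areas[:-1] * 1.02)
        # hull over a slab reflects the slab's widest radius: compare the
        # extreme slabs against the analytic radius at the slab edges
        r_at = lambda z: 0.3 + (0.12 - 0.3) * z / 2.0
        assert areas[0] == pytest.approx(np.pi * r_at(0.0) ** 2, rel=0.05)
        assert areas[-1] == pytest.approx(np.pi * r_at(1.9) ** 2, rel=0.05)

    def test_single_slab(self, tube_phantom):
        mesh, _ = tube_phantom
        aligned, _ = rm.align_longitudinal(rm.mesh_to_pointcloud(mesh))
        cfg = MorphometryConfig(species="rat", increment=10.0)
        profile = rm.slice_profile(aligned, cfg)
        assert profile.n_sections == 1
        assert profile.areas[0] == pytest.approx(np.pi * 0.09, rel=0.02)

    def test_sparse_slab_warns_zero(self, caplog):
        pts = np.array(
            [[0, 0, 0.0], [1, 0, 0.0], [0, 1, 0.0], [0.5, 0.5, 0.0], [0.2, 0.2, 1.0]]
        )
        cloud = PointCloud(points=pts)
        cfg = MorphometryConfig(species="rat", increment=0.5)
        with caplog.at_level("WARNING", logger="rodentmorph.ligament"):
            profile = rm.slice_profile(cloud, cfg)
        assert 0.0 in profile.areas


def _profile_from_areas(areas, dz=1.0):
    sections = [
        SliceSection(z_lo=i * dz, z_hi=(i + 1) * dz, points2d=np.zeros((3, 2)), area=a)
        for i, a in enumerate(areas)
    ]
    return CsaProfile(
        increment=dz,
        sections=sections,
        method="hull",
        z_min=0.0,
        z_max=len(areas) * dz,
    )


class TestMidsubstance:
    def test_constant_profile(self):
        mean, idx = midsubstance_csa(_profile_from_areas([0.30] * 20), 0.5)
        assert mean == pytest.approx(0.30)
        assert len(idx) == 10

    def test_flared_end_window(self):
        areas = [1.0, 0.5, 0.3, 0.3, 0.3, 0.3, 0.5, 1.0]
        mean, idx = midsubstance_csa(_profile_from_areas(areas), 0.5)
        assert idx == [2, 3, 4, 5]
        assert mean == pytest.approx(0.30)

    def test_full_fraction_is_identity(self):
        areas = [1.0, 2.0, 3.0, 4.0]
        mean, idx = midsubstance_csa(_profile_from_areas(areas), 1.0)
        assert mean == pytest.approx(2.5)
        assert idx == [0, 1, 2, 3]

    def test_no_center_in_window(self):
        # two slab centers at 0.5 and 1.5; a vanishing window around 1.0
        # contains neither (pathologically coarse increment)
        profile = _profile_from_areas([1.0, 1.0])
        with pytest.raises(ValueError):
            midsubstance_csa(profile, 1e-9)


class TestNormalizeCsa:
    @pytest.mark.parametrize(
        "csa,footprint,expected",
        [(0.26, 33.35, 0.78), (0.054, 5.67, 0.95)],
    )
    def test_published_arithmetic(self, csa, footprint, expected):
        """Normalized CSA reproduces the published worked examples after
        rounding to two decimals."""
        assert round_half_away(normalize_csa(csa, footprint), 2) == expected

    def test_linearity(self, rng):
        x, f = rng.uniform(0.1, 1.0), rng.uniform(1.0, 40.0)
        assert normalize_csa(x, 2 * f) == pytest.approx(normalize_csa(x, f) / 2)

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_nonpositive_footprint(self, bad):
        with pytest.raises(ValueError):
            normalize_csa(0.3, bad)


class TestPipelineProperties:
    def test_rotation_invariance(self, tube_phantom, rng):
        mesh, manifest = tube_phantom
        cfg = MorphometryConfig(species="rat")
        base = _pipeline_csa(mesh, cfg)
        for _ in range(5):
            R = _random_rotation(rng)
            rotated = TriangleMesh(vertices=mesh.vertices @ R.T, faces=mesh.faces)
            csa = _pipeline_csa(rotated, cfg)
            assert abs(csa - base) / base < 0.01

    @pytest.mark.parametrize("r0,species", [(0.1, "mouse"), (0.2, "mouse"), (0.3, "rat")])
    def test_tube_recovery(self, r0, species):
        spec = rm.LigamentPhantomSpec(
            length=2.0,
            radius_profile={"kind": "constant", "r0": r0},
            cross_section={"kind": "circle", "r": r0},
            seed=11,
        )
        mesh, _ = rm.make_ligament_phantom(spec)
        cfg = MorphometryConfig(species=species, increment=0.05)
        assert _pipeline_csa(mesh, cfg) == pytest.approx(np.pi * r0**2, rel=0.02)

    def test_flared_ends_excluded(self):
        """Enlarging only the end quarters leaves midsubstance CSA nearly
        unchanged (insertion regions are excluded)."""
        plain = rm.LigamentPhantomSpec(seed=5)
        flared = rm.LigamentPhantomSpec(
            radius_profile={
                "kind": "flared",
                "r_mid": 0.3,
                "r_end": 0.45,
                "flare_fraction": 0.22,
            },
            seed=5,
        )
        cfg = MorphometryConfig(species="rat")
        csa_plain = _pipeline_csa(rm.make_ligament_phantom(plain)[0], cfg)
        csa_flared = _pipeline_csa(rm.make_ligament_phantom(flared)[0], cfg)
        assert abs(csa_flared - csa_plain) / csa_plain < 0.01

    def test_hull_vs_plane_convex(self, tube_phantom):
        mesh, _ = tube_phantom
        cloud = rm.mesh_to_pointcloud(mesh)
        aligned, frame = rm.align_longitudinal(cloud)
        amesh = TriangleMesh(vertices=frame.apply(mesh.vertices), faces=mesh.faces)
        hull = rm.slice_profile(aligned, MorphometryConfig(species="rat")).areas
        plane = rm.slice_profile(
            aligned,
            MorphometryConfig(species="rat", csa_method="plane_intersection"),
            mesh=amesh,
        ).areas
        np.testing.assert_allclose(hull, plane, rtol=0.01)

    def test_hull_bounds_crescent(self, crescent_phantom):
        mesh, manifest = crescent_phantom
        cloud = rm.mesh_to_pointcloud(mesh)
        aligned, frame = rm.align_longitudinal(cloud)
        amesh = TriangleMesh(vertices=frame.apply(mesh.vertices), faces=mesh.faces)
        hull = rm.slice_profile(aligned, MorphometryConfig(species="rat")).areas
        plane = rm.slice_profile(
            aligned,
            MorphometryConfig(species="rat", csa_method="plane_intersection"),
            mesh=amesh,
        ).areas
        assert np.all(hull >= plane - 1e-9)
        # plane-intersection recovers the analytic lune area
        mid = len(plane) // 2
        assert plane[mid] == pytest.approx(manifest.values["base_csa_mm2"], rel=0.01)
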