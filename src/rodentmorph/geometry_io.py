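"""Mesh and label-volume I/O plus mask <-> surface conversion.

STL coordinates are interpreted as millimetres throughout (STL carries no
unit metadata; all source geometry is exported in mm). Masks are converted
to surfaces the same way the segmentation software does: Gaussian smoothing
of the binary occupancy (sigma expressed in voxels) followed by extraction
of the 0.5 iso-surface.
"""

from __future__ import annotations

import json
import os
from typing import Optional, Tuple

import numpy as np
import trimesh
from scipy import ndimage
from skimage import measure as skmeasure

from .types import (
    EmptyMeshError,
    EmptyVolumeError,
    GeometryError,
    LabelVolume,
    MeshFormatError,
    PointCloud,
    TriangleMesh,
)

__all__ = [
    "read_stl",
    "write_stl",
    "mesh_from_volume",
    "voxelize",
    "mesh_to_pointcloud",
    "read_label_volume",
    "write_label_volume",
]


def _dedupe_exact(vertices: np.ndarray, faces: np.ndarray):
    """Merge vertices with exactly identical coordinates and re-index faces."""
    unique, inverse = np.unique(vertices, axis=0, return_inverse=True)
    return unique, inverse[faces]


def read_stl(path, name: str = "other") -> TriangleMesh:
    """Read a binary or ASCII STL file into a :class:`TriangleMesh`.

    Vertices are deduplicated by exact coordinate match (STL stores each
    triangle's corners independently), and units are taken as mm.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with open(path, "rb") as fh:
        head = fh.read(84)
    if not head.lstrip()[:5] == b"solid":
        # binary layout: 80-byte header, uint32 count, 50 bytes per facet
        if len(head) < 84:
            raise MeshFormatError(f"truncated binary STL file {path!s}")
        n_facets = int(np.frombuffer(head[80:84], dtype="<u4")[0])
        expected = 84 + 50 * n_facets
        if os.path.getsize(path) < expected:
            raise MeshFormatError(
                f"truncated binary STL file {path!s}: header declares "
                f"{n_facets} facets but the file is too short"
            )
    try:
        tm = trimesh.load_mesh(path, file_type="stl", process=False)
    except Exception as exc:  # noqa: BLE001 - normalize loader failures
        raise MeshFormatError(f"cannot parse STL file {path!s}: {exc}") from exc
    if not hasattr(tm, "faces") or len(tm.faces) == 0:
        raise EmptyMeshError(f"STL file {path!s} contains no triangles")
    vertices, faces = _dedupe_exact(np.asarray(tm.vertices), np.asarray(tm.faces))
    return TriangleMesh(vertices=vertices, faces=faces, name=name)


def write_stl(mesh: TriangleMesh, path, dialect: str = "binary") -> None:
    """Write a mesh as STL; ``dialect`` selects binary or ascii."""
    if dialect not in ("binary", "ascii"):
        raise ValueError("dialect must be 'binary' or 'ascii'")
    tm = mesh.to_trimesh()
    file_type = "stl" if dialect == "binary" else "stl_ascii"
    data = trimesh.exchange.stl.export_stl(tm) if dialect == "binary" else (
        trimesh.exchange.stl.export_stl_ascii(tm)
    )
    mode = "wb" if dialect == "binary" else "w"
    try:
        with open(path, mode) as fh:
            fh.write(data)
    except OSError as exc:
        raise OSError(f"cannot write STL to {path!s}: {exc}") from exc


def _staircase_surface(mask: np.ndarray, voxel_size: float) -> TriangleMesh:
    """Exact boundary surface of the voxel set: each voxel is a cube of
    side voxel_size centered on its sample point; exposed faces are
    emitted as two triangles each."""
    quads = []  # (4, 3) corner lattice coordinates, outward CCW
    # corner offsets of the +d and -d faces of a unit cube centered at 0
    for d in range(3):
        for sign in (+1, -1):
            shifted = np.zeros_like(mask)
            src = [slice(None)] * 3
            dst = [slice(None)] * 3
            if sign > 0:
                src[d], dst[d] = slice(1, None), slice(None, -1)
            else:
                src[d], dst[d] = slice(None, -1), slice(1, None)
            shifted[tuple(dst)] = mask[tuple(src)]
            exposed = (mask == 1) & (shifted == 0)
            idx = np.argwhere(exposed).astype(float)
            if len(idx) == 0:
                continue
            e1, e2 = [(k) for k in range(3) if k != d]
            for i in idx:
                c = i.copy()
                c[d] += 0.5 * sign
                corners = np.tile(c, (4, 1))
                corners[:, e1] += [-0.5, 0.5, 0.5, -0.5]
                corners[:, e2] += [-0.5, -0.5, 0.5, 0.5]
                if (sign > 0) == (((d + 1) % 3) == e1):
                    quads.append(corners)
                else:
                    quads.append(corners[::-1])
    corner_pts = np.vstack(quads)
    uniq, inv = np.unique(np.round(corner_pts * 2).astype(int), axis=0, return_inverse=True)
    tris = []
    for q in range(len(quads)):
        a, b, c, d4 = inv[4 * q : 4 * q + 4]
        tris.append([a, b, c])
        tris.append([a, c, d4])
    verts = uniq / 2.0 * voxel_size
    mesh = TriangleMesh(vertices=verts, faces=np.asarray(tris), name="other")
    tm = mesh.to_trimesh()
    if tm.volume < 0:
        tm.invert()
    return TriangleMesh.from_trimesh(tm)


def mesh_from_volume(vol: LabelVolume, sigma: float = 1.0) -> TriangleMesh:
    """Convert a binary mask to a smoothed surface mesh.

    For ``sigma > 0`` the mask is Gaussian-filtered with ``sigma`` (in
    voxels) and the 0.5 iso-surface extracted by marching cubes, scaled
    to mm. ``sigma = 0`` yields the exact voxel staircase surface (a
    single voxel becomes a cube of side voxel_size).
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if vol.n_foreground == 0:
        raise EmptyVolumeError("label volume has no foreground voxels")
    if sigma == 0:
        return _staircase_surface(vol.mask, vol.voxel_size)
    field = ndimage.gaussian_filter(np.pad(vol.mask.astype(float), 2), sigma=sigma)
    verts, faces, _, _ = skmeasure.marching_cubes(field, level=0.5)
    verts = (verts - 2.0) * vol.voxel_size  # undo padding, scale to mm
    mesh = TriangleMesh(vertices=verts, faces=faces, name="other")
    tm = mesh.to_trimesh()
    if tm.volume < 0:
        tm.invert()
    return TriangleMesh.from_trimesh(tm)


def _column_crossings(vertices, faces, xs, ys):
    """z-values where vertical rays through the grid columns (xs x ys)
    cross the surface, as flat arrays (ix, iy, z)."""
    tri = vertices[faces]
    ix_all, iy_all, z_all = [], [], []
    for t in tri:
        p0, p1, p2 = t
        lo_x, hi_x = min(p0[0], p1[0], p2[0]), max(p0[0], p1[0], p2[0])
        lo_y, hi_y = min(p0[1], p1[1], p2[1]), max(p0[1], p1[1], p2[1])
        i0, i1 = np.searchsorted(xs, [lo_x, hi_x])
        j0, j1 = np.searchsorted(ys, [lo_y, hi_y])
        if i0 == i1 or j0 == j1:
            continue
        gx, gy = np.meshgrid(xs[i0:i1], ys[j0:j1], indexing="ij")
        # barycentric coordinates in the xy-projection
        d = (p1[1] - p2[1]) * (p0[0] - p2[0]) + (p2[0] - p1[0]) * (p0[1] - p2[1])
        if d == 0:
            continue  # triangle vertical in z; contributes no column crossing
        w0 = ((p1[1] - p2[1]) * (gx - p2[0]) + (p2[0] - p1[0]) * (gy - p2[1])) / d
        w1 = ((p2[1] - p0[1]) * (gx - p2[0]) + (p0[0] - p2[0]) * (gy - p2[1])) / d
        w2 = 1.0 - w0 - w1
        inside = (w0 >= 0) & (w1 >= 0) & (w2 >= 0)
        if not inside.any():
            continue
        z = w0 * p0[2] + w1 * p1[2] + w2 * p2[2]
        ii, jj = np.nonzero(inside)
        ix_all.append(ii + i0)
        iy_all.append(jj + j0)
        z_all.append(z[inside])
    if not ix_all:
        return (np.empty(0, int), np.empty(0, int), np.empty(0))
    return (
        np.concatenate(ix_all),
        np.concatenate(iy_all),
        np.concatenate(z_all),
    )


def voxelize(mesh: TriangleMesh, voxel_size: float) -> LabelVolume:
    """Voxelize a watertight mesh: a voxel is occupied iff its center lies
    inside the surface. The grid is padded by at least one voxel.

    Occupancy is decided by ray-crossing parity along z-columns of voxel
    centers; the columns carry a sub-voxel irrational offset so rays
    never hit mesh edges or vertices exactly.
    """
    if voxel_size <= 0:
        raise ValueError("voxel_size must be positive")
    tm = mesh.to_trimesh()
    if not tm.is_watertight:
        raise GeometryError("voxelize requires a watertight mesh")
    lo = tm.bounds[0] - voxel_size
    hi = tm.bounds[1] + voxel_size
    counts = np.ceil((hi - lo) / voxel_size).astype(int)
    axes = [lo[k] + (np.arange(counts[k]) + 0.5) * voxel_size for k in range(3)]
    # degenerate-ray guard: offset the ray grid (not the reported centers)
    xs = axes[0] + voxel_size * 1e-6 * np.sqrt(2.0)
    ys = axes[1] + voxel_size * 1e-6 * np.sqrt(3.0)
    ix, iy, zc = _column_crossings(mesh.vertices, mesh.faces, xs, ys)
    mask = np.zeros(tuple(counts), dtype=np.uint8)
    if len(ix):
        order = np.lexsort((zc, iy, ix))
        ix, iy, zc = ix[order], iy[order], zc[order]
        col_id = ix * counts[1] + iy
        starts = np.r_[0, np.flatnonzero(np.diff(col_id)) + 1, len(col_id)]
        zs = axes[2]
        for s, e in zip(starts[:-1], starts[1:]):
            crossings = zc[s:e]
            below = np.searchsorted(crossings, zs, side="right")
            mask[ix[s], iy[s], :] = below % 2
    return LabelVolume(mask=mask, voxel_size=voxel_size)


def mesh_to_pointcloud(mesh: TriangleMesh) -> PointCloud:
    """Expose the unique mesh vertices as a surface point cloud."""
    unique = np.unique(mesh.vertices, axis=0)
    return PointCloud(points=unique, source=mesh.name)


def _check_isotropic(zooms, path) -> float:
    zooms = np.asarray(zooms[:3], dtype=float)
    if not np.allclose(zooms, zooms[0], rtol=1e-4):
        raise ValueError(
            f"label volume {path!s} has anisotropic voxels {zooms}; "
            "isotropic voxels are required"
        )
    return float(zooms[0])


def read_label_volume(
    path,
    axis_labels: Optional[Tuple[str, str, str]] = None,
    voxel_size: Optional[float] = None,
) -> LabelVolume:
    """Read a binary mask from NIfTI (.nii/.nii.gz), NRRD (.nrrd), or the
    raw-array fallback (.npz with a JSON sidecar giving voxel_size and
    axis_labels).

    ``axis_labels`` must be supplied when the container carries no
    orientation metadata usable for plane naming; the default assumes the
    third array axis stacks axial slices.
    """
    path = str(path)
    if path.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(path)
        data = np.asarray(img.dataobj)
        vs = voxel_size or _check_isotropic(img.header.get_zooms(), path)
    elif path.endswith(".nrrd"):
        import SimpleITK as sitk

        img = sitk.ReadImage(path)
        data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)  # back to x,y,z order
        vs = voxel_size or _check_isotropic(img.GetSpacing(), path)
    elif path.endswith(".npz"):
        with np.load(path) as npz:
            data = npz["mask"]
        sidecar = os.path.splitext(path)[0] + ".json"
        meta = {}
        if os.path.exists(sidecar):
            with open(sidecar) as fh:
                meta = json.load(fh)
        vs = voxel_size or meta.get("voxel_size")
        if vs is None:
            raise ValueError("raw-array volume needs voxel_size (sidecar or argument)")
        axis_labels = axis_labels or tuple(meta.get("axis_labels", ()) ) or None
    else:
        raise ValueError(f"unsupported label volume format: {path!s}")
    labels = tuple(axis_labels) if axis_labels else ("sagittal", "coronal", "axial")
    data = (np.asarray(data) > 0.5).astype(np.uint8)
    return LabelVolume(mask=data, voxel_size=float(vs), axis_labels=labels)


def write_label_volume(vol: LabelVolume, path) -> None:
    """Write a mask as NIfTI, NRRD, or npz+sidecar, by file extension."""
    path = str(path)
    if path.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.diag([vol.voxel_size] * 3 + [1.0])
        nib.save(nib.Nifti1Image(vol.mask.astype(np.uint8), affine), path)
    elif path.endswith(".nrrd"):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(vol.mask.transpose(2, 1, 0).astype(np.uint8))
        img.SetSpacing((vol.voxel_size,) * 3)
        sitk.WriteImage(img, path)
    elif path.endswith(".npz"):
        np.savez_compressed(path, mask=vol.mask)
        sidecar = os.path.splitext(path)[0] + ".json"
        with open(sidecar, "w") as fh:
            json.dump(
                {"voxel_size": vol.voxel_size, "axis_labels": list(vol.axis_labels)},
                fh,
            )
    else:
        raise ValueError(f"unsupported label volume format: {path!s}")
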