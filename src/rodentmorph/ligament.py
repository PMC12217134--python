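"""Ligament cross-sectional-area morphometry.

A segmented ligament surface is aligned so its longitudinal axis lies on
+z (first principal component of the vertex cloud), sectioned into fixed
z-increments matching the scan resolution (0.1 mm rat, 0.05 mm mouse),
each slab flattened onto the transverse plane and its CSA computed, and
the midsubstance CSA summarized as the unweighted mean over the middle
50% of the length — excluding the flared regions near the bony
insertions. CSA may optionally be normalized to tibial-plateau footprint
area to compare across species.
"""

from __future__ import annotations

import logging
from decimal import Decimal, ROUND_HALF_UP
from typing import List, Optional, Tuple

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.stats import skew

from .types import (
    AlignmentFrame,
    CsaProfile,
    DegenerateAxisError,
    MorphometryConfig,
    PointCloud,
    SliceSection,
    TriangleMesh,
)

logger = logging.getLogger(__name__)

__all__ = [
    "align_longitudinal",
    "slice_profile",
    "midsubstance_csa",
    "normalize_csa",
    "round_half_away",
]

#: minimum ratio of first to second principal extent for a defined axis
MIN_EXTENT_RATIO = 1.2


def align_longitudinal(cloud: PointCloud) -> Tuple[PointCloud, AlignmentFrame]:
    """Rotate a ligament point cloud so its longitudinal axis is +z.

    The longitudinal axis is the first principal direction of the centered
    cloud. The sign of +z is fixed deterministically by requiring the
    skewness of the aligned z-coordinates to be nonnegative.

    Raises
    ------
    DegenerateAxisError
        If the dominant principal extent is less than 1.2x the second
        (no meaningful long axis, e.g. a sphere-like cloud).
    """
    pts = cloud.points
    if len(pts) < 4:
        raise ValueError("need at least 4 points to define an axis")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    # principal directions of the covariance via SVD
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    if svals[1] <= 0 or svals[0] / svals[1] < MIN_EXTENT_RATIO:
        raise DegenerateAxisError(
            f"principal extent ratio {svals[0] / max(svals[1], 1e-300):.3f} "
            f"< {MIN_EXTENT_RATIO}; cloud has no dominant longitudinal axis"
        )
    v_long, v2, v3 = vt[0], vt[1], vt[2]
    rotation = np.vstack([v2, v3, v_long])  # rows: new x, y, z in input coords
    if np.linalg.det(rotation) < 0:
        rotation[1] = -rotation[1]
    z = centered @ rotation[2]
    if skew(z) < 0:
        # flip z; flip x too so the determinant stays +1
        rotation = np.vstack([-rotation[0], rotation[1], -rotation[2]])
    frame = AlignmentFrame(rotation=rotation, centroid=centroid)
    aligned = PointCloud(points=centered @ rotation.T, source=cloud.source)
    return aligned, frame


def _hull_area(points2d: np.ndarray) -> float:
    """Area of the 2D convex hull; 0 for degenerate (collinear) slabs."""
    if len(points2d) < 3:
        return 0.0
    try:
        return float(ConvexHull(points2d).volume)  # 2D "volume" is area
    except QhullError:
        return 0.0


def _plane_section_area(mesh_tm, z_mid: float) -> float:
    """Total enclosed area of the mesh / mid-plane intersection loops."""
    section = mesh_tm.section(plane_origin=[0.0, 0.0, z_mid], plane_normal=[0, 0, 1])
    if section is None:
        return 0.0
    planar, _ = section.to_2D()
    return float(planar.area)


def slice_profile(
    cloud: PointCloud,
    cfg: MorphometryConfig,
    mesh: Optional[TriangleMesh] = None,
) -> CsaProfile:
    """Section an aligned cloud along z and compute per-slab CSA.

    Slabs are half-open ``[z_lo, z_lo + dz)`` starting at the minimum z;
    the final partial slab is kept if it holds at least 3 points. Per-slab
    area uses ``cfg.csa_method``:

    - ``hull``: area of the 2D convex hull of the slab's points flattened
      along z (orthographic projection, no obliquity correction);
    - ``plane_intersection``: enclosed area of the polygon loops where the
      aligned source ``mesh`` crosses the slab's mid-plane (requires the
      mesh argument, expressed in the same aligned frame).

    Slabs with fewer than 3 points get area 0 with a logged warning.
    """
    pts = cloud.points
    dz = cfg.increment
    z = pts[:, 2]
    z_min, z_max = float(z.min()), float(z.max())
    if cfg.csa_method == "plane_intersection":
        if mesh is None:
            raise ValueError("plane_intersection requires the aligned source mesh")
        mesh_tm = mesh.to_trimesh()

    # tolerance keeps an extent that is an exact multiple of dz from
    # spilling a degenerate extra slab through float rounding
    n_slabs = max(1, int(np.ceil((z_max - z_min) / dz - 1e-9)))
    # points exactly at z_max fall into the last slab
    idx = np.minimum(((z - z_min) / dz).astype(int), n_slabs - 1)

    sections: List[SliceSection] = []
    for i in range(n_slabs):
        sel = idx == i
        slab_pts = pts[sel][:, :2]
        z_lo = z_min + i * dz
        z_hi = min(z_lo + dz, z_max) if i == n_slabs - 1 else z_lo + dz
        if len(slab_pts) < 3:
            if i == n_slabs - 1 and (z_max - z_lo) < dz:
                continue  # drop a sparse partial remainder slab
            logger.warning(
                "slab [%0.4f, %0.4f) has %d point(s); area set to 0",
                z_lo,
                z_hi,
                len(slab_pts),
            )
            area = 0.0
        elif cfg.csa_method == "hull":
            area = _hull_area(slab_pts)
        else:
            area = _plane_section_area(mesh_tm, 0.5 * (z_lo + z_hi))
        sections.append(SliceSection(z_lo=z_lo, z_hi=z_hi, points2d=slab_pts, area=area))

    if not sections:
        raise ValueError("no usable slabs; increment too large or cloud too sparse")
    profile = CsaProfile(
        increment=dz,
        sections=sections,
        method=cfg.csa_method,
        z_min=z_min,
        z_max=z_max,
    )
    mid, included = midsubstance_csa(profile, cfg.midsubstance_fraction)
    profile.midsubstance_csa = mid
    profile.midsubstance_indices = included
    return profile


def midsubstance_csa(profile: CsaProfile, fraction: float = 0.5) -> Tuple[float, list]:
    """Mean CSA over slabs whose center lies in the middle ``fraction`` of
    the longitudinal extent.

    Returns the mean and the indices of the included sections. The window
    is ``[z_min + (1-f)/2 * L, z_min + (1+f)/2 * L]`` (closed) with L the
    full z-extent.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    if profile.n_sections == 0:
        raise ValueError("profile has no sections")
    length = profile.z_max - profile.z_min
    lo = profile.z_min + 0.5 * (1.0 - fraction) * length
    hi = profile.z_min + 0.5 * (1.0 + fraction) * length
    included = [
        i for i, s in enumerate(profile.sections) if lo <= s.center <= hi
    ]
    if not included:
        raise ValueError(
            "no slab center falls inside the midsubstance window; "
            "increment is too coarse for this tissue"
        )
    mean_area = float(np.mean([profile.sections[i].area for i in included]))
    return mean_area, included


def normalize_csa(csa: float, footprint: float) -> float:
    """Ligament CSA as a percentage of tibial-plateau footprint area."""
    if footprint <= 0:
        raise ValueError("footprint area must be positive")
    return 100.0 * csa / footprint


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (report-table convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
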