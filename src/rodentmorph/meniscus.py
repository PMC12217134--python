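"""Regional meniscus morphometry: widths and heights at the anterior horn,
central region, and posterior horn.

The meniscus is a C-shaped wedge between femur and tibia. After rotation
to an anatomic frame (x = medial-lateral, y = anterior-posterior,
z = proximal-distal), the central region is read from the middle three
coronal slices at the circumferential apex (the medial-most or
lateral-most portion for medial and lateral menisci respectively), and
each horn from the middle three sagittal slices at that horn's free end.
Within each slice, heights and widths are taken as ten equally spaced
span measurements across the slice.
"""

from __future__ import annotations

import logging
from typing import List, Sequence

import numpy as np

from .types import (
    AnatomicFrame,
    MeniscusRegionMeasure,
    MeniscusSliceMeasure,
    PointCloud,
    TriangleMesh,
)

logger = logging.getLogger(__name__)

__all__ = [
    "orient_meniscus",
    "select_region_slices",
    "measure_slice",
    "summarize_region",
    "measure_regions",
]

REGIONS = ("anterior_horn", "central", "posterior_horn")


def orient_meniscus(mesh: TriangleMesh, frame: AnatomicFrame) -> PointCloud:
    """Express the meniscus vertices in the anatomic frame.

    The frame's rotation maps input coordinates onto anatomic axes; frame
    validity (orthonormal, det +1) is enforced by :class:`AnatomicFrame`.
    """
    unique = np.unique(mesh.vertices, axis=0)
    return PointCloud(points=unique @ frame.rotation.T, source=mesh.name)


def _three_slabs(values: np.ndarray, center: float, thickness: float):
    """Indices of points in 3 contiguous slabs of ``thickness`` centered on
    ``center`` along the coordinate ``values``."""
    edges = center + thickness * np.array([-1.5, -0.5, 0.5, 1.5])
    return [
        np.flatnonzero((values >= edges[k]) & (values < edges[k + 1]))
        for k in range(3)
    ]


def select_region_slices(
    cloud: PointCloud,
    region: str,
    slice_thickness: float,
    side: str,
) -> List[np.ndarray]:
    """Pick the three tissue slices for one anatomical region.

    central
        Three coronal slabs (stacked along y) centered at the y-position
        of the circumferential extremum: the point with maximal x for a
        lateral meniscus, minimal x for a medial one. Slab points are
        flattened to (x, z).
    anterior_horn / posterior_horn
        Three sagittal slabs (stacked along x) centered at the x-position
        of the horn's y-extremum, clamped so all three slabs lie on
        tissue (at a free end the window shifts inward minimally). The
        horn is the subset of points beyond the centroid toward anterior
        (+y) or posterior (-y). Slab points are flattened to (y, z).

    Raises ``ValueError`` if any slab holds fewer than 3 points (slice
    thickness too coarse for the tissue) or the slabs exceed the span.
    """
    if region not in REGIONS:
        raise ValueError(f"unknown region {region!r}")
    if side not in ("medial", "lateral"):
        raise ValueError("side must be 'medial' or 'lateral'")
    if slice_thickness <= 0:
        raise ValueError("slice_thickness must be positive")
    pts = cloud.points

    def _clamped_center(values: np.ndarray, center: float) -> float:
        lo = values.min() + 1.5 * slice_thickness
        hi = values.max() - 1.5 * slice_thickness
        if lo > hi:
            raise ValueError(
                f"3 slices of {slice_thickness} mm exceed the tissue span "
                f"{values.max() - values.min():.3f} mm"
            )
        return float(np.clip(center, lo, hi))

    if region == "central":
        apex_idx = np.argmax(pts[:, 0]) if side == "lateral" else np.argmin(pts[:, 0])
        center_y = _clamped_center(pts[:, 1], pts[apex_idx, 1])
        groups = _three_slabs(pts[:, 1], center_y, slice_thickness)
        flat_cols = (0, 2)  # coronal slice -> (x, z)
    else:
        centroid_y = pts[:, 1].mean()
        if region == "anterior_horn":
            horn = pts[pts[:, 1] > centroid_y]
            ext_idx = np.argmax(horn[:, 1])
        else:
            horn = pts[pts[:, 1] < centroid_y]
            ext_idx = np.argmin(horn[:, 1])
        center_x = _clamped_center(horn[:, 0], horn[ext_idx, 0])
        groups = _three_slabs(horn[:, 0], center_x, slice_thickness)
        pts = horn
        flat_cols = (1, 2)  # sagittal slice -> (y, z)

    slabs = []
    for k, idx in enumerate(groups):
        if len(idx) < 3:
            raise ValueError(
                f"{region} slab {k} contains {len(idx)} point(s); "
                "slice thickness too coarse for this resolution"
            )
        slabs.append(pts[idx][:, flat_cols])
    return slabs


def measure_slice(
    points2d: np.ndarray, n_stations: int = 10, mode: str = "max"
) -> MeniscusSliceMeasure:
    """Ten equally spaced height and width measurements across one slice.

    Heights: the in-plane horizontal extent is split into ``n_stations``
    equal bins; each station's height is the vertical span of the points
    in its bin. Widths mirror this with vertical bins and horizontal
    spans. The slice-level width/height is the ``mode`` aggregation (max
    by default, mean available) over stations. Empty stations record 0
    with a warning.
    """
    points2d = np.asarray(points2d, dtype=float)
    if len(points2d) < 3:
        raise ValueError("need at least 3 points to measure a slice")
    if n_stations < 1:
        raise ValueError("n_stations must be >= 1")
    if mode not in ("max", "mean"):
        raise ValueError("mode must be 'max' or 'mean'")
    h, v = points2d[:, 0], points2d[:, 1]

    def spans(coord, other):
        lo, hi = coord.min(), coord.max()
        edges = np.linspace(lo, hi, n_stations + 1)
        idx = np.minimum(np.searchsorted(edges, coord, side="right") - 1, n_stations - 1)
        out = np.zeros(n_stations)
        for s in range(n_stations):
            sel = idx == s
            if not np.any(sel):
                logger.warning("station %d is empty; span recorded as 0", s)
                continue
            out[s] = other[sel].max() - other[sel].min()
        return out

    station_heights = spans(h, v)
    station_widths = spans(v, h)
    agg = np.max if mode == "max" else np.mean
    return MeniscusSliceMeasure(
        plane="",
        station_widths=station_widths,
        station_heights=station_heights,
        slice_width=float(agg(station_widths)),
        slice_height=float(agg(station_heights)),
        mode=mode,
    )


def summarize_region(
    slices: Sequence[MeniscusSliceMeasure], mode: str = "max", region: str = "central"
) -> MeniscusRegionMeasure:
    """Average the three per-slice values into one regional width/height.

    The per-slice value is the ``mode`` aggregation over that slice's ten
    stations; the region value is the arithmetic mean over the 3 slices.
    """
    if len(slices) != 3:
        raise ValueError(f"a region summarizes exactly 3 slices, got {len(slices)}")
    if mode not in ("max", "mean"):
        raise ValueError("mode must be 'max' or 'mean'")
    agg = np.max if mode == "max" else np.mean
    widths = [float(agg(s.station_widths)) for s in slices]
    heights = [float(agg(s.station_heights)) for s in slices]
    return MeniscusRegionMeasure(
        region=region,
        slice_measures=list(slices),
        width=float(np.mean(widths)),
        height=float(np.mean(heights)),
        mode=mode,
    )


def measure_regions(
    cloud: PointCloud,
    side: str,
    slice_thickness: float,
    n_stations: int = 10,
    mode: str = "max",
) -> List[MeniscusRegionMeasure]:
    """Convenience driver: all three regional measures for one meniscus."""
    results = []
    for region in REGIONS:
        slabs = select_region_slices(cloud, region, slice_thickness, side)
        plane = "coronal" if region == "central" else "sagittal"
        slices = []
        for slab in slabs:
            m = measure_slice(slab, n_stations=n_stations, mode=mode)
            m.plane = plane
            slices.append(m)
        results.append(summarize_region(slices, mode=mode, region=region))
    return results
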