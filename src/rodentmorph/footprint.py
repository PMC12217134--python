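"""Tibial plateau footprint area, the bone-size reference used to
normalize ligament CSA across species.

The footprint is a single axial segmentation slice of the tibia at the
widest point of the plateau; its area is the segmented volume divided by
the voxel height, i.e. ``n_voxels * voxel_size**2`` for isotropic voxels.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .stats import bland_altman, rank_sum
from .types import EmptyVolumeError, FootprintResult, LabelVolume, MultiSliceError

__all__ = ["plateau_footprint", "compare_footprints"]


def plateau_footprint(vol: LabelVolume) -> FootprintResult:
    """Footprint area of a single-axial-slice tibial segmentation.

    The segmented volume is ``n_voxels * voxel_size**3``; dividing by the
    axial voxel height gives ``n_voxels * voxel_size**2``.

    Raises
    ------
    EmptyVolumeError
        If the mask has no foreground.
    MultiSliceError
        If foreground spans more than one axial index (the offending
        indices are reported).
    """
    n = vol.n_foreground
    if n == 0:
        raise EmptyVolumeError("footprint mask is empty")
    other_axes = tuple(k for k in range(3) if k != vol.axial_axis)
    per_slice = vol.mask.sum(axis=other_axes)
    occupied = np.flatnonzero(per_slice)
    if len(occupied) > 1:
        raise MultiSliceError(occupied.tolist())
    area = (n * vol.voxel_size**3) / vol.voxel_size
    return FootprintResult(area=float(area), n_voxels=int(n), voxel_size=vol.voxel_size)


def compare_footprints(mri_areas: Sequence[float], ct_areas: Sequence[float]):
    """Agreement between paired MRI- and microCT-measured plateau areas.

    Returns a (StatResult, AgreementResult) pair: a paired two-sided
    rank-sum test of the differences and the Bland-Altman bias with 95%
    limits of agreement.
    """
    a = np.asarray(mri_areas, dtype=float)
    b = np.asarray(ct_areas, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired area lists must have equal length")
    if len(a) < 3:
        raise ValueError("need at least 3 paired measurements")
    test = rank_sum(a, b, paired=True)
    agreement = bland_altman(a, b)
    return test, agreement
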