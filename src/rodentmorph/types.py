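"""Core domain containers shared across the morphometry pipeline.

Geometry is always expressed in millimetres. Surface meshes come from
manual segmentation of high-field MRI scans (or from the synthetic phantom
generators); label volumes are binary segmentation masks with isotropic
voxels (0.1 mm for rat scans, 0.05 mm for mouse scans).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

TISSUE_NAMES = (
    "ACL",
    "PCL",
    "MCL",
    "LCL",
    "medial_meniscus",
    "lateral_meniscus",
    "tibia",
    "other",
)

ANATOMICAL_PLANES = ("axial", "coronal", "sagittal")


class MeshFormatError(ValueError):
    """Raised when an STL file cannot be parsed."""


class EmptyMeshError(ValueError):
    """Raised when a mesh has no triangles."""


class GeometryError(ValueError):
    """Raised for geometric preconditions (e.g. non-watertight input)."""


class EmptyVolumeError(ValueError):
    """Raised when a label volume contains no foreground voxels."""


class DegenerateAxisError(ValueError):
    """Raised when a point cloud has no dominant longitudinal axis."""


class MultiSliceError(ValueError):
    """Raised when a footprint mask spans more than one axial slice."""

    def __init__(self, indices: Sequence[int]):
        self.indices = list(indices)
        super().__init__(
            f"footprint mask must occupy a single axial slice; "
            f"found foreground on axial indices {self.indices}"
        )


class DesignError(ValueError):
    """Raised for incomplete/unbalanced factorial layouts."""


@dataclass
class TriangleMesh:
    """Triangle surface mesh of one tissue, coordinates in mm."""

    vertices: np.ndarray  # (n, 3) float
    faces: np.ndarray  # (m, 3) int
    name: str = "other"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be an (m, 3) array")
        if len(self.faces) == 0:
            raise EmptyMeshError("mesh has no triangles")
        if not np.all(np.isfinite(self.vertices)):
            raise ValueError("mesh vertices contain non-finite coordinates")
        if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
            raise ValueError("face indices out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def bounds(self) -> np.ndarray:
        return np.vstack([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    def to_trimesh(self):
        import trimesh

        return trimesh.Trimesh(
            vertices=self.vertices.copy(), faces=self.faces.copy(), process=False
        )

    @classmethod
    def from_trimesh(cls, tm, name: str = "other") -> "TriangleMesh":
        return cls(vertices=np.asarray(tm.vertices), faces=np.asarray(tm.faces), name=name)


@dataclass
class LabelVolume:
    """Binary 3D segmentation mask with isotropic voxels.

    ``axis_labels`` names the anatomical plane stacked along each array
    axis, e.g. the default ``("sagittal", "coronal", "axial")`` means axis 2
    indexes axial slices.
    """

    mask: np.ndarray
    voxel_size: float
    axis_labels: Tuple[str, str, str] = ("sagittal", "coronal", "axial")

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask)
        if self.mask.ndim != 3:
            raise ValueError("mask must be a 3D array")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        vals = np.unique(self.mask)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask must contain only 0/1 values")
        if sorted(self.axis_labels) != sorted(ANATOMICAL_PLANES):
            raise ValueError(
                f"axis_labels must be a permutation of {ANATOMICAL_PLANES}"
            )
        self.mask = self.mask.astype(np.uint8)

    @property
    def axial_axis(self) -> int:
        return self.axis_labels.index("axial")

    @property
    def n_foreground(self) -> int:
        return int(self.mask.sum())


@dataclass
class PointCloud:
    """Surface point cloud of one tissue (mm)."""

    points: np.ndarray  # (n, 3)
    source: str = "other"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (n, 3) array")
        if len(self.points) == 0:
            raise ValueError("point cloud is empty")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("point cloud contains non-finite coordinates")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class AlignmentFrame:
    """Rigid transform taking input coordinates into the aligned frame.

    Aligned coordinates are ``rotation @ (x - centroid)`` with the
    longitudinal axis mapped to +z.
    """

    rotation: np.ndarray  # (3, 3), orthonormal, det +1
    centroid: np.ndarray  # (3,)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, dtype=float) - self.centroid) @ self.rotation.T

    def invert(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation + self.centroid


@dataclass
class SliceSection:
    """One transverse slab of an aligned ligament."""

    z_lo: float
    z_hi: float
    points2d: np.ndarray  # (n, 2) flattened slab points
    area: float  # mm^2

    @property
    def center(self) -> float:
        return 0.5 * (self.z_lo + self.z_hi)


@dataclass
class CsaProfile:
    """Ordered per-slab cross-sectional areas along the longitudinal axis."""

    increment: float
    sections: list  # of SliceSection, ordered distal -> proximal
    method: str  # "hull" or "plane_intersection"
    z_min: float
    z_max: float
    midsubstance_csa: Optional[float] = None
    midsubstance_indices: Optional[list] = None

    @property
    def areas(self) -> np.ndarray:
        return np.array([s.area for s in self.sections])

    @property
    def n_sections(self) -> int:
        return len(self.sections)


@dataclass
class MorphometryConfig:
    """Per-species analysis settings.

    The slab increment follows the scan resolution: 0.1 mm for rat,
    0.05 mm for mouse. The midsubstance is the middle 50% of the
    longitudinal extent; areas outside it (near the bony insertions) are
    excluded from the summary CSA.
    """

    species: str = "rat"
    increment: Optional[float] = None
    midsubstance_fraction: float = 0.50
    csa_method: str = "hull"
    alpha: float = 0.05

    SPECIES_INCREMENT = {"rat": 0.1, "mouse": 0.05}

    def __post_init__(self) -> None:
        if self.species not in self.SPECIES_INCREMENT:
            raise ValueError(f"unknown species {self.species!r}")
        if self.increment is None:
            self.increment = self.SPECIES_INCREMENT[self.species]
        if self.increment <= 0:
            raise ValueError("increment must be positive")
        if not (0 < self.midsubstance_fraction <= 1):
            raise ValueError("midsubstance_fraction must lie in (0, 1]")
        if self.csa_method not in ("hull", "plane_intersection"):
            raise ValueError(f"unknown csa_method {self.csa_method!r}")


@dataclass
class AnatomicFrame:
    """Rotation to anatomic axes: x = medial-lateral, y = anterior-posterior,
    z = proximal-distal; plus the side of the joint the tissue comes from."""

    rotation: np.ndarray
    side: str  # "medial" or "lateral"

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        if self.rotation.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if self.side not in ("medial", "lateral"):
            raise ValueError("side must be 'medial' or 'lateral'")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation must have determinant +1")


@dataclass
class MeniscusSliceMeasure:
    """Station-wise spans across one meniscal tissue slice."""

    plane: str  # "coronal" or "sagittal"
    station_widths: np.ndarray  # (n_stations,)
    station_heights: np.ndarray  # (n_stations,)
    slice_width: float
    slice_height: float
    mode: str = "max"


@dataclass
class MeniscusRegionMeasure:
    """Aggregated width/height for one anatomical region of a meniscus."""

    region: str  # anterior_horn | central | posterior_horn
    slice_measures: list  # 3 MeniscusSliceMeasure
    width: float
    height: float
    mode: str = "max"


@dataclass
class FootprintResult:
    """Tibial plateau footprint from a single-axial-slice segmentation."""

    area: float  # mm^2
    n_voxels: int
    voxel_size: float


@dataclass
class StatResult:
    """One hypothesis-test outcome (omnibus, post hoc, or gate)."""

    test_name: str
    statistic: float
    df: object  # float or (float, float)
    p_value: float
    p_adjusted: Optional[float] = None
    alpha: float = 0.05
    label: str = ""

    def __post_init__(self) -> None:
        if self.p_adjusted is None:
            self.p_adjusted = self.p_value

    @property
    def significant(self) -> bool:
        return self.p_adjusted < self.alpha


@dataclass
class AgreementResult:
    """Agreement between two raters/methods on paired measurements."""

    n_pairs: int
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    icc: float = float("nan")
    icc_defined: bool = True
    slope: float = float("nan")
    means: Optional[np.ndarray] = None
    diffs: Optional[np.ndarray] = None


def format_p(p: float, floor: float = 1e-3) -> str:
    """Report-style p formatting: values below the floor print as '<0.001'."""
    if p < floor:
        return f"<{floor:g}"
    return f"{p:.3g}"
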