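"""Core value types shared across the quantification stages.

Conventions
-----------
* Confocal stacks are stored as numpy arrays with axes ``(z, y, x)`` (the
  TIFF / imaging convention).  Physical voxel sizes are carried in the same
  ``(z, y, x)`` order; helper constructors accept the more common
  ``x/y/z`` microscope notation.
* All stack/ROI indices are 0-based with half-open bounds.
* Electron-microscopy particle coordinates are planar and expressed in nm;
  areas are reported in µm².
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

try:  # shapely is a hard dependency, but keep the import local to geometry use
    from shapely.geometry import Polygon
except ImportError:  # pragma: no cover
    Polygon = None  # type: ignore

#: Default confocal voxel size in µm, x/y/z order.
DEFAULT_VOXEL_SIZE_XYZ_UM = (0.089, 0.089, 0.313)

AXES = ("z", "y", "x")


def _axis_index(axis: str) -> int:
    if axis not in AXES:
        raise ValueError(f"projection axis must be one of {AXES}, got {axis!r}")
    return AXES.index(axis)


@dataclass(frozen=True)
class ImageStack:
    """A single-channel 3D intensity grid with physical voxel sizes.

    Parameters
    ----------
    data:
        Non-negative intensities, axes ``(z, y, x)``.
    voxel_size_zyx_um:
        Physical voxel edge lengths in µm, same axis order as ``data``.
    """

    data: np.ndarray
    voxel_size_zyx_um: tuple[float, float, float]

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"stack must be 3D (z, y, x); got shape {data.shape}")
        if any(s < 3 for s in data.shape):
            raise ValueError(f"stack needs at least 3 voxels per axis; got {data.shape}")
        if len(self.voxel_size_zyx_um) != 3 or any(v <= 0 for v in self.voxel_size_zyx_um):
            raise ValueError("voxel sizes must be three positive lengths (µm)")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "voxel_size_zyx_um", tuple(float(v) for v in self.voxel_size_zyx_um))

    @classmethod
    def from_xyz(cls, data: np.ndarray, voxel_size_xyz_um: Sequence[float] = DEFAULT_VOXEL_SIZE_XYZ_UM) -> "ImageStack":
        """Build a stack from ``(z, y, x)`` data and x/y/z voxel sizes."""
        vx, vy, vz = voxel_size_xyz_um
        return cls(data=data, voxel_size_zyx_um=(vz, vy, vx))

    @property
    def voxel_size_xyz_um(self) -> tuple[float, float, float]:
        vz, vy, vx = self.voxel_size_zyx_um
        return (vx, vy, vz)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class MembraneROI:
    """An axis-aligned sub-volume marking one membrane segment.

    ``bounds_zyx`` is ``((z0, z1), (y0, y1), (x0, x1))``, 0-based half-open.
    ``projection_axis`` is the membrane-normal direction along which the
    maximum-intensity projection is taken.
    """

    id: str
    bounds_zyx: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]
    projection_axis: str = "z"
    polarity_label: str = "unspecified"
    cell_id: Optional[str] = None

    def __post_init__(self) -> None:
        _axis_index(self.projection_axis)
        if self.polarity_label not in ("apical", "basal", "lateral", "unspecified"):
            raise ValueError(f"unknown polarity label {self.polarity_label!r}")
        for lo, hi in self.bounds_zyx:
            if hi <= lo or lo < 0:
                raise ValueError(f"bad ROI bounds {self.bounds_zyx}")

    @property
    def projection_axis_index(self) -> int:
        return _axis_index(self.projection_axis)

    def validate_against(self, stack: ImageStack) -> None:
        for (lo, hi), n in zip(self.bounds_zyx, stack.shape):
            if hi > n:
                raise ValueError(f"ROI {self.id!r} bounds {self.bounds_zyx} exceed stack shape {stack.shape}")
        in_plane = [hi - lo for ax, (lo, hi) in enumerate(self.bounds_zyx) if ax != self.projection_axis_index]
        if any(n < 3 for n in in_plane):
            raise ValueError(f"ROI {self.id!r} projected plane must be at least 3x3 pixels")

    def extract(self, stack: ImageStack) -> np.ndarray:
        self.validate_against(stack)
        (z0, z1), (y0, y1), (x0, x1) = self.bounds_zyx
        return stack.data[z0:z1, y0:y1, x0:x1]


@dataclass(frozen=True)
class PlaneImage:
    """A 2D image with physical pixel sizes (µm per in-plane axis)."""

    data: np.ndarray
    pixel_size_um: tuple[float, float]

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 2:
            raise ValueError("plane image must be 2D")
        if any(p <= 0 for p in self.pixel_size_um):
            raise ValueError("pixel sizes must be positive")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "pixel_size_um", tuple(float(p) for p in self.pixel_size_um))

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size_um[0] * self.pixel_size_um[1]


@dataclass(frozen=True)
class ClusterCall:
    """One detected confocal cluster: a strict local maximum plus its
    growing-window size class."""

    peak: tuple[int, int]  # (row, col) in the projected plane
    n_max: int  # largest passing window radius, in pixels
    side_px: int  # size class, 2 * n_max + 1
    diameter_um: float
    capped: bool = False  # growth stopped at the configured cap or the border
    low_contrast: bool = False  # surrogate flag for manual false-positive curation


@dataclass(frozen=True)
class DensityResult:
    roi_id: str
    n_peaks: int
    n_retained: int
    membrane_area_um2: float
    density_per_um2: float

    def __post_init__(self) -> None:
        if self.membrane_area_um2 <= 0:
            raise ValueError("membrane area must be positive")
        if self.density_per_um2 < 0:
            raise ValueError("density cannot be negative")


@dataclass(frozen=True)
class EMImage:
    """A 2D electron micrograph with a verified physical calibration."""

    data: np.ndarray
    scale_nm_per_px: float

    def __post_init__(self) -> None:
        if np.asarray(self.data).ndim != 2:
            raise ValueError("EM image must be 2D")
        if self.scale_nm_per_px <= 0:
            raise ValueError("scale must be positive (nm per pixel)")


@dataclass(frozen=True)
class CellAxis:
    """Apical–basal axis of a cell, in the particle coordinate frame (nm).

    ``direction`` points from the apical toward the basal edge; axial
    coordinates are projections onto it.  ``apical_edge_nm`` and
    ``basal_edge_nm`` are the axial coordinates of the two polar edges.
    """

    direction: tuple[float, float] = (0.0, 1.0)
    apical_edge_nm: float = 0.0
    basal_edge_nm: float = 10_000.0

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        norm = float(np.hypot(*d))
        if norm == 0:
            raise ValueError("axis direction must be a nonzero vector")
        object.__setattr__(self, "direction", (float(d[0] / norm), float(d[1] / norm)))
        if self.basal_edge_nm == self.apical_edge_nm:
            raise ValueError("apical and basal edges must differ")

    @property
    def length_nm(self) -> float:
        return abs(self.basal_edge_nm - self.apical_edge_nm)

    @property
    def midline_nm(self) -> float:
        return 0.5 * (self.apical_edge_nm + self.basal_edge_nm)

    def axial_coordinate(self, xy_nm: np.ndarray) -> np.ndarray:
        """Signed axial coordinate (nm) of points, in edge units."""
        xy = np.atleast_2d(np.asarray(xy_nm, dtype=float))
        return xy @ np.asarray(self.direction)

    def distance_from_apical(self, xy_nm: np.ndarray) -> np.ndarray:
        s = self.axial_coordinate(xy_nm)
        sign = 1.0 if self.basal_edge_nm > self.apical_edge_nm else -1.0
        return sign * (s - self.apical_edge_nm)


@dataclass(frozen=True)
class ParticleSet:
    """Gold-particle planar coordinates (nm) plus cell-edge geometry."""

    xy_nm: np.ndarray  # (N, 2)
    ids: Optional[np.ndarray] = None
    region: Optional["Polygon"] = None  # analyzed-area polygon, nm
    axis: Optional[CellAxis] = None
    source: str = "frl"  # "iem" | "frl"

    def __post_init__(self) -> None:
        xy = np.asarray(self.xy_nm, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "xy_nm", xy)
        ids = self.ids
        if ids is None:
            ids = np.arange(len(xy))
        ids = np.asarray(ids)
        if len(ids) != len(xy):
            raise ValueError("ids and coordinates must have equal length")
        object.__setattr__(self, "ids", ids)
        if self.source not in ("iem", "frl"):
            raise ValueError("source must be 'iem' or 'frl'")

    def __len__(self) -> int:
        return len(self.xy_nm)

    @property
    def region_area_um2(self) -> float:
        if self.region is None:
            raise ValueError("particle set carries no analyzed-region polygon")
        return float(self.region.area) / 1e6  # nm² -> µm²


@dataclass(frozen=True)
class ParticleGroup:
    """One single-linkage group of gold particles."""

    members: tuple[int, ...]
    group_class: str  # "scattered" | "doublet" | "cluster"
    diameter_nm: float
    centroid_nm: tuple[float, float]
    domain: Optional[str] = None

    def __post_init__(self) -> None:
        expected = classify_size(len(self.members))
        if self.group_class != expected:
            raise ValueError(f"class {self.group_class!r} inconsistent with size {len(self.members)}")

    @property
    def size(self) -> int:
        return len(self.members)


def classify_size(size: int) -> str:
    """Map a group size to the scattered / doublet / cluster nomenclature."""
    if size <= 0:
        raise ValueError("group size must be positive")
    if size == 1:
        return "scattered"
    if size == 2:
        return "doublet"
    return "cluster"


@dataclass(frozen=True)
class PolarityResult:
    """Apical-to-lateral membrane signal ratio for one cell."""

    apical_mean: float
    lateral_mean: float
    ratio: float
    background_mean: Optional[float] = None
    cell_id: Optional[str] = None


@dataclass(frozen=True)
class GroupComparison:
    label_a: str
    label_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    test: str
    statistic: float
    p_value: float
    stars: str
    flags: tuple[str, ...] = field(default_factory=tuple)
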