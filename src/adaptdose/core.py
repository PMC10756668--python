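"""Core domain types shared by every stage of the pipeline.

Conventions (fixed across the package):

* Patient coordinates are millimetres; axis order is (x, y, z).
* Grids are axis-aligned with identity orientation; a voxel's coordinate
  is its centre; voxel indices are 0-based.
* Dose is in Gy on the total-course (five-fraction) scale.
* Volumes are absolute cubic centimetres (cc).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np


class AdaptdoseError(Exception):
    """Base class for package errors."""


class FormatError(AdaptdoseError):
    """A file does not conform to the expected format."""


class UnsupportedGeometryError(AdaptdoseError):
    """Oblique or otherwise unsupported grid geometry."""


class ConsistencyError(AdaptdoseError):
    """Manifest and array payload of a case bundle disagree."""


class PlanningError(AdaptdoseError):
    """The surrogate planner cannot produce a plan (e.g. empty target)."""


class GenerationError(AdaptdoseError):
    """Synthetic anatomy generation failed a geometric constraint."""


@dataclass(frozen=True)
class ImageGrid3D:
    """Axis-aligned voxel lattice in patient coordinates.

    Parameters
    ----------
    origin
        Patient coordinate (mm) of the centre of voxel (0, 0, 0).
    spacing
        Voxel size (mm) along (x, y, z); all components > 0.
    shape
        Number of voxels along (x, y, z); all components >= 1.
    """

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.origin) != 3 or len(self.spacing) != 3 or len(self.shape) != 3:
            raise ValueError("origin, spacing and shape must be 3-vectors")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if any(n < 1 for n in self.shape):
            raise ValueError(f"shape must be >= 1 per axis, got {self.shape}")
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        object.__setattr__(self, "spacing", tuple(float(v) for v in self.spacing))
        object.__setattr__(self, "shape", tuple(int(v) for v in self.shape))

    @property
    def voxel_volume_cc(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def axis_coords(self, axis: int) -> np.ndarray:
        """Voxel-centre coordinates (mm) along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Map (N, 3) mm points to fractional voxel indices."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """True where a point lies inside the grid's bounding box (voxel
        centres extended by half a voxel)."""
        idx = self.world_to_index(points)
        lo = idx >= -0.5
        hi = idx <= np.asarray(self.shape) - 0.5
        return np.all(lo & hi, axis=1)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ImageGrid3D):
            return NotImplemented
        return (
            np.allclose(self.origin, other.origin)
            and np.allclose(self.spacing, other.spacing)
            and self.shape == other.shape
        )

    def __hash__(self) -> int:
        return hash((self.origin, self.spacing, self.shape))


class OrganClass(str, enum.Enum):
    TARGET = "target"
    GI_OAR = "gi_oar"
    OTHER = "other"


#: The four gastrointestinal organs at risk evaluated by the pipeline.
GI_ORGANS = ("duodenum", "stomach", "colon", "small_bowel")

#: Name used for the clinical target volume in every synthetic structure set.
TARGET_NAME = "ctv"


@dataclass
class Structure:
    """Named organ delineation: a stack of closed planar polygons.

    ``contours`` maps slice z-position (mm) to a list of (n, 2) float arrays
    of (x, y) vertices.  Polygons are implicitly closed (first vertex is not
    repeated).  Several polygons may share a slice; containment parity
    (even-odd rule) defines the interior.
    """

    name: str
    organ_class: OrganClass
    contours: list[tuple[float, list[np.ndarray]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        cleaned: list[tuple[float, list[np.ndarray]]] = []
        for z, polys in self.contours:
            arrs = []
            for p in polys:
                a = np.asarray(p, dtype=float)
                if a.ndim != 2 or a.shape[1] != 2 or a.shape[0] < 3:
                    raise ValueError(
                        f"structure {self.name!r}: polygon on slice z={z} must be "
                        f"(n>=3, 2), got shape {a.shape}"
                    )
                arrs.append(a)
            cleaned.append((float(z), arrs))
        cleaned.sort(key=lambda t: t[0])
        zs = [z for z, _ in cleaned]
        if len(zs) != len(set(zs)):
            raise ValueError(f"structure {self.name!r}: duplicate slice z-positions")
        self.contours = cleaned

    @property
    def z_positions(self) -> list[float]:
        return [z for z, _ in self.contours]

    def translated(self, t: np.ndarray) -> "Structure":
        """Rigidly translate all contours by t = (tx, ty, tz) mm."""
        t = np.asarray(t, dtype=float)
        new = [
            (z + t[2], [p + t[:2] for p in polys]) for z, polys in self.contours
        ]
        return Structure(self.name, self.organ_class, new)

    def all_vertices(self) -> np.ndarray:
        """All vertices as an (N, 3) array (x, y, z) in mm."""
        rows = []
        for z, polys in self.contours:
            for p in polys:
                rows.append(np.column_stack([p, np.full(len(p), z)]))
        if not rows:
            return np.empty((0, 3))
        return np.vstack(rows)


@dataclass
class StructureSet:
    """Ordered collection of structures; order is file/manifest order."""

    structures: list[Structure] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s.name for s in self.structures]
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate structure names: {dup}")

    def __iter__(self) -> Iterator[Structure]:
        return iter(self.structures)

    def __len__(self) -> int:
        return len(self.structures)

    def __getitem__(self, name: str) -> Structure:
        for s in self.structures:
            if s.name == name:
                return s
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(s.name == name for s in self.structures)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.structures]

    @property
    def target(self) -> Structure:
        for s in self.structures:
            if s.organ_class is OrganClass.TARGET:
                return s
        raise KeyError("structure set has no target structure")

    @property
    def gi_oars(self) -> list[Structure]:
        return [s for s in self.structures if s.organ_class is OrganClass.GI_OAR]


@dataclass
class DoseGrid:
    """Scalar dose field (Gy, total-course scale) on an axis-aligned grid.

    ``dose`` has shape ``grid.shape`` with axis order (x, y, z).
    """

    grid: ImageGrid3D
    dose: np.ndarray

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        if self.dose.shape != tuple(self.grid.shape):
            raise ValueError(
                f"dose shape {self.dose.shape} != grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.dose)):
            raise ValueError("dose values must be finite")
        if np.any(self.dose < 0):
            raise ValueError("dose values must be >= 0")


@dataclass
class BinaryMask:
    """Voxelised occupancy on a reference grid; source of all cc volumes."""

    grid: ImageGrid3D
    occupancy: np.ndarray
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        if self.occupancy.shape != tuple(self.grid.shape):
            raise ValueError(
                f"occupancy shape {self.occupancy.shape} != grid shape "
                f"{self.grid.shape}"
            )

    @property
    def volume_cc(self) -> float:
        return float(self.occupancy.sum()) * self.grid.voxel_volume_cc

    def __and__(self, other: "BinaryMask") -> "BinaryMask":
        self._check(other)
        return BinaryMask(self.grid, self.occupancy & other.occupancy)

    def __or__(self, other: "BinaryMask") -> "BinaryMask":
        self._check(other)
        return BinaryMask(self.grid, self.occupancy | other.occupancy)

    def __sub__(self, other: "BinaryMask") -> "BinaryMask":
        self._check(other)
        return BinaryMask(self.grid, self.occupancy & ~other.occupancy)

    def _check(self, other: "BinaryMask") -> None:
        if self.grid != other.grid:
            raise ValueError("masks are defined on different grids")


@dataclass
class CaseBundle:
    """One (patient, fraction) unit: anatomies plus scheduled/adapted dose.

    ``pre_anatomy`` is the anatomy the plan was adapted on; ``post_anatomy``
    is the anatomy at the end of delivery.  Both dose grids share one
    :class:`ImageGrid3D`.
    """

    patient_id: str
    fraction_index: int
    pre_anatomy: StructureSet
    post_anatomy: StructureSet
    scheduled_dose: DoseGrid
    adapted_dose: DoseGrid
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fraction_index < 1:
            raise ValueError("fraction_index is 1-based and must be >= 1")
        if set(self.pre_anatomy.names) != set(self.post_anatomy.names):
            raise ValueError(
                "pre- and post-treatment anatomies must contain the same organs"
            )
        if self.scheduled_dose.grid != self.adapted_dose.grid:
            raise ValueError("scheduled and adapted dose must share one grid")

    @property
    def grid(self) -> ImageGrid3D:
        return self.scheduled_dose.grid
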