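"""Domain model for cytoskeleton quantification scenes.

A *scene* is one quantification unit: typically a single tomogram of the
cell periphery, holding traced filament centerlines (actin filaments and
microtubules), membrane models (the ventral membrane "VM" that contacts the
support, and optionally the dorsal membrane), and organelle sets such as
insulin secretory granules (ISGs).

Conventions
-----------
* Coordinates are 3D points in **nanometres**, ordered ``(x, y, z)``.
  Nanometres are the sole internal unit; voxel→nm conversion happens once,
  at I/O time.
* Voxel masks use ``(z, y, x)`` axis order, matching MRC storage with the
  fastest axis last in numpy indexing.
* The VM lies, by convention, in the tomogram XY plane; the +z direction
  points from the VM into the cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .errors import ValidationError

FilamentKind = Literal["actin", "mt"]

#: Segmentation-unit geometry used as the cylinder volume model:
#: actin units are 60 nm long, 8 nm diameter; MT units 100 nm, 15 nm.
SEGMENT_LENGTH_NM = {"actin": 60.0, "mt": 100.0}
SEGMENT_DIAMETER_NM = {"actin": 8.0, "mt": 15.0}


@dataclass(frozen=True)
class Filament:
    """One traced filament centerline: an ordered 3D polyline in nm."""

    id: str
    kind: str
    points: np.ndarray  # (N, 3) float, nm, (x, y, z)

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        if self.kind not in ("actin", "mt"):
            raise ValidationError(f"filament {self.id!r}: unknown kind {self.kind!r}")
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValidationError(f"filament {self.id!r}: points must be (N, 3)")
        if pts.shape[0] < 2:
            raise ValidationError(f"filament {self.id!r}: needs >= 2 points")
        if not np.all(np.isfinite(pts)):
            raise ValidationError(f"filament {self.id!r}: non-finite coordinates")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(seg == 0):
            raise ValidationError(
                f"filament {self.id!r}: consecutive duplicate points"
            )

    @property
    def arc_length_nm(self) -> float:
        """Total polyline arc length in nm."""
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    @property
    def endpoints(self) -> tuple[np.ndarray, np.ndarray]:
        return self.points[0], self.points[-1]


@dataclass(frozen=True)
class SceneFrame:
    """Geometry of the tomogram frame: voxel size, dimensions, tilt axis."""

    voxel_size_nm: tuple[float, float, float]  # (x, y, z)
    dims_voxels: tuple[int, int, int]  # (x, y, z)
    tilt_axis: str = "y"
    condition_label: str = ""

    def __post_init__(self):
        vs = tuple(float(v) for v in self.voxel_size_nm)
        dv = tuple(int(d) for d in self.dims_voxels)
        object.__setattr__(self, "voxel_size_nm", vs)
        object.__setattr__(self, "dims_voxels", dv)
        if any(v <= 0 for v in vs):
            raise ValidationError("voxel sizes must be positive")
        if any(d <= 0 for d in dv):
            raise ValidationError("frame dimensions must be positive")
        if self.tilt_axis not in ("x", "y"):
            raise ValidationError(f"tilt axis must be x or y, got {self.tilt_axis!r}")

    @property
    def bounds_nm(self) -> np.ndarray:
        """Physical extent (x, y, z) in nm."""
        return np.array(self.voxel_size_nm) * np.array(self.dims_voxels)

    @property
    def volume_nm3(self) -> float:
        return float(np.prod(self.bounds_nm))


@dataclass(frozen=True)
class MembraneModel:
    """A membrane as an analytic plane or a mask-derived surface point set.

    Exactly one of ``plane`` (a ``(point, unit_normal)`` pair) or
    ``surface_points`` (an ``(N, 3)`` nm point set) is set.
    """

    role: str  # "vm" | "dorsal"
    plane: tuple[np.ndarray, np.ndarray] | None = None
    surface_points: np.ndarray | None = None

    def __post_init__(self):
        if self.role not in ("vm", "dorsal"):
            raise ValidationError(f"membrane role must be vm or dorsal: {self.role!r}")
        if (self.plane is None) == (self.surface_points is None):
            raise ValidationError("exactly one of plane / surface_points required")
        if self.plane is not None:
            point = np.asarray(self.plane[0], dtype=float)
            normal = np.asarray(self.plane[1], dtype=float)
            norm = np.linalg.norm(normal)
            if norm == 0 or not np.isfinite(norm):
                raise ValidationError("plane normal must be nonzero and finite")
            if abs(norm - 1.0) > 1e-9:
                normal = normal / norm
            object.__setattr__(self, "plane", (point, normal))
        else:
            pts = np.asarray(self.surface_points, dtype=float)
            if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] == 0:
                raise ValidationError("surface_points must be a non-empty (N, 3) set")
            object.__setattr__(self, "surface_points", pts)

    @classmethod
    def from_plane(cls, role: str, point: Sequence[float], normal: Sequence[float]):
        return cls(role=role, plane=(np.asarray(point, float), np.asarray(normal, float)))

    @classmethod
    def from_surface_points(cls, role: str, points: np.ndarray):
        return cls(role=role, surface_points=points)

    @classmethod
    def xy_plane(cls, role: str, z_nm: float):
        """The tomogram XY-plane convention: membrane at height ``z_nm``."""
        return cls.from_plane(role, (0.0, 0.0, z_nm), (0.0, 0.0, 1.0))

    def fitted_plane(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(point, unit_normal)``, least-squares fit when mask-derived.

        Raises :class:`ValidationError` when the surface points are
        (near-)collinear so no plane is defined.
        """
        if self.plane is not None:
            return self.plane
        pts = self.surface_points
        centroid = pts.mean(axis=0)
        centered = pts - centroid
        # smallest singular vector = normal of the best-fit plane
        _, s, vt = np.linalg.svd(centered, full_matrices=False)
        if pts.shape[0] < 3 or s[1] < 1e-9 * max(s[0], 1.0):
            raise ValidationError(
                f"membrane {self.role!r}: surface points are collinear, plane fit undefined"
            )
        return centroid, vt[2]


@dataclass(frozen=True)
class OrganelleSet:
    """Organelles (ISGs, lysosomes, ...) as spheres or a voxel mask.

    Exposes a nearest-surface-distance contract via
    :func:`cytoarch.organelles.surface_distances`.
    """

    kind: str  # "isg" | "lysosome" | "other"
    centers: np.ndarray | None = None  # (N, 3) nm
    radii: np.ndarray | None = None  # (N,) nm
    mask: np.ndarray | None = None  # (z, y, x) bool
    frame: SceneFrame | None = None  # required with mask

    def __post_init__(self):
        if self.kind not in ("isg", "lysosome", "other"):
            raise ValidationError(f"unknown organelle kind {self.kind!r}")
        has_spheres = self.centers is not None
        if has_spheres == (self.mask is not None):
            raise ValidationError("exactly one of spheres / mask required")
        if has_spheres:
            centers = np.atleast_2d(np.asarray(self.centers, float))
            radii = np.atleast_1d(np.asarray(self.radii, float))
            if centers.shape[0] != radii.shape[0]:
                raise ValidationError("centers and radii length mismatch")
            if np.any(radii <= 0):
                raise ValidationError("organelle radii must be positive")
            object.__setattr__(self, "centers", centers)
            object.__setattr__(self, "radii", radii)
        else:
            if self.frame is None:
                raise ValidationError("mask representation requires a frame")
            mask = np.asarray(self.mask, bool)
            dims_zyx = tuple(reversed(self.frame.dims_voxels))
            if mask.shape != dims_zyx:
                raise ValidationError(
                    f"mask shape {mask.shape} does not match frame dims (z,y,x) {dims_zyx}"
                )
            object.__setattr__(self, "mask", mask)

    @property
    def is_spheres(self) -> bool:
        return self.centers is not None

    def __len__(self) -> int:
        if self.is_spheres:
            return self.centers.shape[0]
        return int(self.mask.any())


@dataclass
class Scene:
    """A complete quantification unit (one tomogram's worth of annotations)."""

    frame: SceneFrame
    filaments: list[Filament] = field(default_factory=list)
    membranes: list[MembraneModel] = field(default_factory=list)
    organelles: list[OrganelleSet] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        roles = [m.role for m in self.membranes]
        if len(roles) != len(set(roles)):
            raise ValidationError("at most one membrane per role")
        self._warn_out_of_bounds()

    def _warn_out_of_bounds(self):
        hi = self.bounds_with_margin()
        lo = -np.asarray(self.frame.voxel_size_nm)
        for f in self.filaments:
            if np.any(f.points < lo) or np.any(f.points > hi):
                warnings.warn(
                    f"filament {f.id!r} has points outside the frame bounds",
                    stacklevel=3,
                )

    def bounds_with_margin(self) -> np.ndarray:
        return self.frame.bounds_nm + np.asarray(self.frame.voxel_size_nm)

    def membrane(self, role: str) -> MembraneModel | None:
        for m in self.membranes:
            if m.role == role:
                return m
        return None

    def filaments_of(self, kind: str) -> list[Filament]:
        return [f for f in self.filaments if f.kind == kind]

    def organelle_set(self, kind: str) -> OrganelleSet | None:
        for o in self.organelles:
            if o.kind == kind:
                return o
        return None
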