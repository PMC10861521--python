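"""Core geometric kernels: resampling, chords, angles, distances.

All kernels are pure and deterministic, operate in nm, and follow the
pipeline's orientation convention: a filament's orientation is the angle of
its end-to-end *chord* (not local tangents) to the membrane plane, in
[0, 90] degrees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import ValidationError
from .model import Filament, MembraneModel

DEFAULT_RESAMPLE_NM = 4.0  #: resampling interval along arc length


@dataclass(frozen=True)
class ResampledFilament:
    """A filament resampled at fixed arc-length intervals.

    Samples sit at arc positions 0, h, 2h, ... plus the terminal point, so
    the final spacing may be shorter than ``interval_nm`` (remainder rule)
    and total arc length is conserved.
    """

    filament_id: str
    kind: str
    samples: np.ndarray  # (M, 3) nm
    arc_positions: np.ndarray  # (M,) arc-length position of each sample on the curve
    interval_nm: float

    @property
    def arc_length_nm(self) -> float:
        """Arc length covered along the source polyline (exactly conserved)."""
        return float(self.arc_positions[-1] - self.arc_positions[0])


@dataclass(frozen=True)
class ChordVector:
    """End-to-end chord of a filament: unit direction, length, endpoints."""

    filament_id: str
    direction: np.ndarray  # unit 3-vector
    length_nm: float
    endpoints: tuple[np.ndarray, np.ndarray]


def resample_polyline(
    filament: Filament, interval_nm: float = DEFAULT_RESAMPLE_NM
) -> ResampledFilament:
    """Resample a polyline at fixed arc-length spacing.

    The first and last samples coincide with the polyline termini and the
    resampled arc length equals the polyline arc length (the curve is
    re-traced, not approximated by chords between samples beyond the
    original vertices: interpolation is linear within original segments).
    """
    if interval_nm <= 0:
        raise ValidationError("resampling interval must be positive")
    pts = filament.points
    seglen = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    total = cum[-1]
    if total <= 0:
        raise ValidationError(f"filament {filament.id!r}: zero arc length")
    targets = np.arange(0.0, total, interval_nm)
    targets = np.append(targets, total)
    samples = np.column_stack([
        np.interp(targets, cum, pts[:, k]) for k in range(3)
    ])
    samples[0] = pts[0]
    samples[-1] = pts[-1]
    return ResampledFilament(
        filament_id=filament.id, kind=filament.kind,
        samples=samples, arc_positions=targets, interval_nm=float(interval_nm),
    )


def chord_vector(filament: Filament) -> ChordVector:
    """End-to-end chord (last minus first point), as a unit vector + length."""
    first, last = filament.points[0], filament.points[-1]
    delta = last - first
    length = float(np.linalg.norm(delta))
    if length < 1e-12:
        raise ValidationError(
            f"filament {filament.id!r}: coincident termini, chord degenerate"
        )
    return ChordVector(
        filament_id=filament.id, direction=delta / length,
        length_nm=length, endpoints=(first.copy(), last.copy()),
    )


def _as_unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, float)
    n = np.linalg.norm(v)
    if n == 0 or not np.isfinite(n):
        raise ValidationError("zero or non-finite vector")
    if abs(n - 1.0) > 1e-9:
        warnings.warn("non-unit vector normalized", stacklevel=3)
        v = v / n
    return v


def angle_to_plane(v: np.ndarray, membrane: MembraneModel) -> float:
    """Angle (degrees, [0, 90]) between a direction and a membrane plane.

    Computed as arcsin(|v . n|) with n the unit plane normal; invariant to
    v -> -v and to in-plane rotation of v.
    """
    v = _as_unit(v)
    _, normal = membrane.fitted_plane()
    s = min(1.0, abs(float(np.dot(v, normal))))
    return float(np.degrees(np.arcsin(s)))


def pair_angle(v1: np.ndarray, v2: np.ndarray, directed: bool = False) -> float:
    """Angle between two unit vectors, degrees.

    ``directed`` -> arccos(v1 . v2) in [0, 180]; otherwise the undirected
    (axial) angle min(theta, 180 - theta) in [0, 90].
    """
    v1, v2 = _as_unit(v1), _as_unit(v2)
    c = float(np.clip(np.dot(v1, v2), -1.0, 1.0))
    theta = float(np.degrees(np.arccos(c)))
    if directed:
        return theta
    return min(theta, 180.0 - theta)


def min_point_distance(
    A: np.ndarray, B: np.ndarray
) -> tuple[float, tuple[int, int]]:
    """Global minimum Euclidean distance between two point sets.

    Uses a KD-tree; identical to the brute-force all-pairs minimum.
    Returns ``(d_min, (i, j))`` with ``A[i]``, ``B[j]`` the closest pair.
    """
    A = np.atleast_2d(np.asarray(A, float))
    B = np.atleast_2d(np.asarray(B, float))
    if A.size == 0 or B.size == 0:
        raise ValidationError("point sets must be non-empty")
    tree = cKDTree(B)
    d, j = tree.query(A, k=1)
    i = int(np.argmin(d))
    return float(d[i]), (i, int(j[i]))


def nearest_neighbor_distances(
    A: np.ndarray, B: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-point nearest distance from each point of A to the set B."""
    A = np.atleast_2d(np.asarray(A, float))
    B = np.atleast_2d(np.asarray(B, float))
    if A.size == 0 or B.size == 0:
        raise ValidationError("point sets must be non-empty")
    d, j = cKDTree(B).query(A, k=1)
    return np.asarray(d, float), np.asarray(j, int)


def distance_to_membrane(points: np.ndarray, membrane: MembraneModel) -> np.ndarray:
    """Per-point distance (nm, >= 0) from points to a membrane.

    Plane representation: unsigned plane distance. Surface-point
    representation: nearest surface point distance.
    """
    points = np.atleast_2d(np.asarray(points, float))
    if points.size == 0:
        raise ValidationError("empty point set")
    if membrane.plane is not None:
        p0, n = membrane.plane
        return np.abs((points - p0) @ n)
    d, _ = cKDTree(membrane.surface_points).query(points, k=1)
    return np.asarray(d, float)
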