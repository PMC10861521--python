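"""Ventral-membrane anchoring analysis.

A filament is *anchored* when at least one of its termini lies within the
anchoring threshold (default 60 nm, the actin segmentation-unit length) of
the VM — boundary inclusive. Each anchored filament carries a directed
vector from its near endpoint (closest terminus to the VM) to its far
endpoint. Two anchored filaments are *neighbors* when their near endpoints
are strictly closer than the neighbor radius (default 120 nm, twice the
segmentation unit). The directed angle between neighboring vectors, mapped
against each member's orientation to the VM, distinguishes "netlike"
(in-plane crossings, large mutual angles) from "blooming" (co-directed
radial projections, small mutual angles) architectures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .architecture import QUASI_ORTHOGONAL_DEG, halfopen_histogram
from .errors import ValidationError
from .geometry import angle_to_plane, distance_to_membrane, pair_angle
from .model import Filament, MembraneModel

ANCHOR_THRESHOLD_NM = 60.0  #: inclusive
NEIGHBOR_RADIUS_NM = 120.0  #: strict


@dataclass(frozen=True)
class AnchoredFilament:
    """An anchored filament with its near/far endpoints and directed vector."""

    filament_id: str
    near_endpoint: np.ndarray
    far_endpoint: np.ndarray
    vm_distance_nm: float
    directed_vector: np.ndarray  # unit, near -> far
    orientation_deg: float  # chord angle to VM, [0, 90]
    tie_degenerate: bool = False  # both termini equidistant from the VM


@dataclass(frozen=True)
class NeighborPair:
    """Unordered pair of anchored filaments with near-endpoint separation."""

    id_a: str
    id_b: str
    endpoint_separation_nm: float
    directed_angle_deg: float  # angle between near->far vectors, [0, 180]


def classify_anchored(
    filaments: list[Filament],
    membrane: MembraneModel,
    threshold_nm: float = ANCHOR_THRESHOLD_NM,
) -> tuple[list[AnchoredFilament], list[str]]:
    """Split filaments into VM-anchored and not-anchored.

    The anchoring distance is the minimum over the two termini of the
    distance to the VM; <= ``threshold_nm`` (inclusive) is anchored. The
    near endpoint is the closer terminus (first point in stored order on an
    exact tie, with ``tie_degenerate`` set).
    """
    if membrane is None:
        raise ValidationError("no VM membrane in scene")
    anchored: list[AnchoredFilament] = []
    rejected: list[str] = []
    for f in filaments:
        first, last = f.points[0], f.points[-1]
        d = distance_to_membrane(np.vstack([first, last]), membrane)
        if min(d) > threshold_nm:
            rejected.append(f.id)
            continue
        tie = bool(d[0] == d[1])
        if d[0] <= d[1]:
            near, far, dist = first, last, float(d[0])
        else:
            near, far, dist = last, first, float(d[1])
        delta = far - near
        norm = np.linalg.norm(delta)
        if norm < 1e-12:
            raise ValidationError(f"filament {f.id!r}: degenerate chord")
        direction = delta / norm
        anchored.append(AnchoredFilament(
            filament_id=f.id,
            near_endpoint=near.copy(), far_endpoint=far.copy(),
            vm_distance_nm=dist, directed_vector=direction,
            orientation_deg=angle_to_plane(direction, membrane),
            tie_degenerate=tie,
        ))
    return anchored, rejected


def neighbor_pairs(
    anchored: list[AnchoredFilament],
    radius_nm: float = NEIGHBOR_RADIUS_NM,
) -> list[NeighborPair]:
    """All unordered anchored pairs with near endpoints strictly < radius."""
    if len(anchored) < 2:
        return []
    near = np.array([a.near_endpoint for a in anchored])
    tree = cKDTree(near)
    pairs = []
    for i, j in sorted(tree.query_pairs(radius_nm)):
        sep = float(np.linalg.norm(near[i] - near[j]))
        if sep >= radius_nm:  # enforce strict inequality
            continue
        pairs.append(NeighborPair(
            id_a=anchored[i].filament_id, id_b=anchored[j].filament_id,
            endpoint_separation_nm=sep,
            directed_angle_deg=pair_angle(
                anchored[i].directed_vector, anchored[j].directed_vector,
                directed=True,
            ),
        ))
    return pairs


def anchored_angle_map(
    anchored: list[AnchoredFilament],
    pairs: list[NeighborPair],
    bin_deg: float = 15.0,
) -> tuple[pd.DataFrame, dict[str, tuple[np.ndarray, np.ndarray]]]:
    """Directed neighbor angles mapped against member orientations.

    Each pair contributes two samples, one per member (that member's
    orientation to the VM paired with the directed inter-filament angle).
    Returns the sample table plus directed-angle histograms over [0, 180]
    with ``bin_deg`` bins, split by member orientation at 45 deg.
    """
    by_id = {a.filament_id: a for a in anchored}
    rows = []
    for p in pairs:
        for member, partner in ((p.id_a, p.id_b), (p.id_b, p.id_a)):
            rows.append((
                member, partner,
                by_id[member].orientation_deg, p.directed_angle_deg,
                p.endpoint_separation_nm,
            ))
    samples = pd.DataFrame(rows, columns=[
        "filament_id", "partner_id", "orientation_deg",
        "directed_angle_deg", "endpoint_separation_nm",
    ])
    if samples.empty:
        warnings.warn("no neighbor pairs: empty anchored-angle map", stacklevel=2)
    hists = {}
    for name, sel in (
        ("semi_parallel", samples.orientation_deg < QUASI_ORTHOGONAL_DEG),
        ("quasi_orthogonal", samples.orientation_deg >= QUASI_ORTHOGONAL_DEG),
    ):
        vals = samples.loc[sel, "directed_angle_deg"].to_numpy() if len(samples) else []
        hists[name] = halfopen_histogram(vals, bin_deg, lo=0.0, hi=180.0 + bin_deg)
    return samples, hists


def anchored_distance_map(
    anchored: list[AnchoredFilament], pairs: list[NeighborPair]
) -> pd.DataFrame:
    """Near-endpoint separation mapped against member orientation.

    Companion variant to :func:`anchored_angle_map` pairing each member's
    orientation with the pair's endpoint separation instead of the directed
    angle.
    """
    by_id = {a.filament_id: a for a in anchored}
    rows = []
    for p in pairs:
        for member in (p.id_a, p.id_b):
            rows.append((member, by_id[member].orientation_deg,
                         p.endpoint_separation_nm))
    return pd.DataFrame(rows, columns=[
        "filament_id", "orientation_deg", "endpoint_separation_nm",
    ])


def periphery_height(
    vm: MembraneModel | None, dorsal: MembraneModel | None
) -> float:
    """Mean distance from VM surface samples to the dorsal membrane (nm).

    With a plane-represented VM the plane's anchor point is the single
    sample; with a mask-derived VM every surface point contributes.
    """
    if vm is None or dorsal is None:
        raise ValidationError("periphery height needs both vm and dorsal membranes")
    if vm.surface_points is not None:
        samples = vm.surface_points
    else:
        samples = vm.plane[0][None, :]
    return float(distance_to_membrane(samples, dorsal).mean())


def anchored_summary(
    anchored: list[AnchoredFilament], all_filaments: list[Filament]
) -> tuple[int, float]:
    """(count, percent of total) of anchored filaments."""
    if not all_filaments:
        raise ValidationError("no filaments to summarize")
    count = len(anchored)
    return count, 100.0 * count / len(all_filaments)
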