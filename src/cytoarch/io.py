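"""Readers and writers for the formats the pipeline touches.

Supported on-disk formats:

* filament coordinate tables — delimited text with columns
  ``filament_id,kind,x,y,z``, rows grouped and ordered within a filament;
* an ASCII SpatialGraph subset (``define VERTEX/EDGE/POINT`` with
  ``VertexCoordinates``, ``EdgeConnectivity``, ``NumEdgePoints``,
  ``EdgePointCoordinates`` data sections), the common exchange format for
  traced filament graphs;
* MRC volumes (modes 0/1/2, thresholded at > 0 for masks), read and
  written through gemmi; header cell lengths are Å and converted to nm;
* a scene bundle: one directory with a JSON manifest pointing at member
  files.

Unit convention: ``units="voxel"`` coordinates are 0-based voxel indices
located at voxel centers; nm = index x voxel_size. nm is the sole internal
unit after reading.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ConfigurationError, FormatError, ValidationError
from .model import Filament, MembraneModel, OrganelleSet, Scene, SceneFrame

REQUIRED_TABLE_COLUMNS = ("filament_id", "kind", "x", "y", "z")


# ---------------------------------------------------------------------------
# filament coordinate tables
# ---------------------------------------------------------------------------

def read_filament_table(
    path, frame: SceneFrame | None = None, units: str = "nm"
) -> list[Filament]:
    """Read filaments from a CSV/TSV coordinate table.

    Parameters
    ----------
    path
        Delimited text file with header ``filament_id,kind,x,y,z``.
    frame
        Required when ``units="voxel"``; supplies the per-axis voxel size.
    units
        ``"nm"`` (coordinates used as-is) or ``"voxel"`` (0-based voxel
        indices at voxel centers, converted to nm axis-wise).
    """
    if units not in ("nm", "voxel"):
        raise ConfigurationError(f"units must be nm or voxel, got {units!r}")
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in REQUIRED_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if units == "voxel":
        if frame is None:
            raise ConfigurationError("voxel units require a SceneFrame")
        scale = np.asarray(frame.voxel_size_nm)
        df = df.assign(x=df.x * scale[0], y=df.y * scale[1], z=df.z * scale[2])

    filaments = []
    bad: list[str] = []
    # preserve first-appearance order of ids and within-id row order
    for fid, grp in df.groupby("filament_id", sort=False):
        pts = grp[["x", "y", "z"]].to_numpy(float)
        if pts.shape[0] < 2:
            bad.append(str(fid))
            continue
        kinds = grp["kind"].unique()
        if len(kinds) != 1:
            raise FormatError(f"{path}: filament {fid!r} has mixed kinds {list(kinds)}")
        filaments.append(Filament(id=str(fid), kind=str(kinds[0]), points=pts))
    if bad:
        raise ValidationError(f"{path}: filaments with < 2 points: {bad}")
    return filaments


def write_filament_table(filaments: list[Filament], path) -> None:
    rows = []
    for f in filaments:
        for p in f.points:
            rows.append((f.id, f.kind, p[0], p[1], p[2]))
    pd.DataFrame(rows, columns=list(REQUIRED_TABLE_COLUMNS)).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# ASCII SpatialGraph subset
# ---------------------------------------------------------------------------

def read_spatialgraph(path) -> list[Filament]:
    """Read filaments from an ASCII SpatialGraph file (one per edge).

    Edge point lists are concatenated in stored order; coordinates are taken
    as nm. Dangling edge references and empty point sections raise
    :class:`FormatError`.
    """
    text = Path(path).read_text()
    counts = {}
    for section in ("VERTEX", "EDGE", "POINT"):
        m = re.search(rf"define\s+{section}\s+(\d+)", text)
        if not m:
            raise FormatError(f"{path}: missing 'define {section}'")
        counts[section] = int(m.group(1))
    if counts["POINT"] == 0:
        raise FormatError(f"{path}: empty POINT section")

    # map data-section markers (@k) to field names
    fields = {}
    for m in re.finditer(
        r"(VERTEX|EDGE|POINT)\s*\{\s*(?:float|int)\[?\d*\]?\s+(\w+)\s*\}\s*@(\d+)",
        text,
    ):
        fields[m.group(2)] = (m.group(1), int(m.group(3)))
    for needed in ("VertexCoordinates", "EdgeConnectivity", "NumEdgePoints",
                   "EdgePointCoordinates"):
        if needed not in fields:
            raise FormatError(f"{path}: missing data field {needed}")

    # split the data part into @k blocks
    blocks = {}
    for m in re.finditer(r"^@(\d+)\s*$", text, flags=re.M):
        start = m.end()
        nxt = re.search(r"^@\d+\s*$", text[start:], flags=re.M)
        end = start + nxt.start() if nxt else len(text)
        tokens = text[start:end].split()
        try:
            blocks[int(m.group(1))] = (
                np.array(tokens, dtype=float) if tokens else np.empty(0)
            )
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric data in block @{m.group(1)}") from exc

    def block(name, shape):
        _, marker = fields[name]
        if marker not in blocks:
            raise FormatError(f"{path}: data block @{marker} ({name}) missing")
        arr = blocks[marker]
        try:
            return arr.reshape(shape)
        except ValueError as exc:
            raise FormatError(f"{path}: wrong element count in {name}") from exc

    n_vertex, n_edge, n_point = counts["VERTEX"], counts["EDGE"], counts["POINT"]
    block("VertexCoordinates", (n_vertex, 3))  # validated but unused below
    connectivity = block("EdgeConnectivity", (n_edge, 2)).astype(int)
    n_edge_points = block("NumEdgePoints", (n_edge,)).astype(int)
    edge_points = block("EdgePointCoordinates", (n_point, 3))

    if connectivity.size and (connectivity.min() < 0 or connectivity.max() >= n_vertex):
        raise FormatError(f"{path}: edge references a missing vertex")
    if n_edge_points.sum() != n_point:
        raise FormatError(f"{path}: NumEdgePoints does not sum to POINT count")

    filaments = []
    offset = 0
    for i, npts in enumerate(n_edge_points):
        pts = edge_points[offset:offset + npts]
        offset += npts
        filaments.append(Filament(id=f"edge{i}", kind="actin", points=pts))
    return filaments


def write_spatialgraph(filaments: list[Filament], path) -> None:
    """Write filaments as an ASCII SpatialGraph (one edge per filament)."""
    n_edge = len(filaments)
    vertices = []
    connectivity = []
    for f in filaments:
        connectivity.append((len(vertices), len(vertices) + 1))
        vertices.append(f.points[0])
        vertices.append(f.points[-1])
    n_point = sum(len(f.points) for f in filaments)
    lines = [
        "# ASCII SpatialGraph 2.0",
        "",
        f"define VERTEX {len(vertices)}",
        f"define EDGE {n_edge}",
        f"define POINT {n_point}",
        "",
        'Parameters { ContentType "HxSpatialGraph" }',
        "",
        "VERTEX { float[3] VertexCoordinates } @1",
        "EDGE { int[2] EdgeConnectivity } @2",
        "EDGE { int NumEdgePoints } @3",
        "POINT { float[3] EdgePointCoordinates } @4",
        "",
        "@1",
    ]
    lines += [f"{v[0]:.9f} {v[1]:.9f} {v[2]:.9f}" for v in vertices]
    lines += ["", "@2"]
    lines += [f"{a} {b}" for a, b in connectivity]
    lines += ["", "@3"]
    lines += [str(len(f.points)) for f in filaments]
    lines += ["", "@4"]
    for f in filaments:
        lines += [f"{p[0]:.9f} {p[1]:.9f} {p[2]:.9f}" for p in f.points]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# MRC volumes
# ---------------------------------------------------------------------------

def read_volume_mask(
    path, voxel_size_nm: tuple[float, float, float] | None = None,
    transpose: bool = True,
) -> tuple[np.ndarray, SceneFrame]:
    """Read an MRC volume as a boolean mask (> 0) plus its frame.

    The returned mask uses ``(z, y, x)`` axis order (``transpose=False``
    keeps the file's x-fastest order for foreign files). Voxel size comes
    from the header (Å, converted to nm), with ``voxel_size_nm`` as the
    fallback when the header records zero.
    """
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"{path}: not a readable MRC volume: {exc}") from exc
    arr = np.array(m.grid, copy=True)  # (x, y, z), x fastest
    if arr.ndim != 3:
        raise FormatError(f"{path}: expected a 3D volume, got {arr.ndim}D")
    spacing_ang = np.array(m.grid.spacing)  # (x, y, z) in Å
    if not np.all(spacing_ang > 0):  # catches zero, negative and NaN headers
        if voxel_size_nm is None:
            raise ConfigurationError(
                f"{path}: header voxel size is zero and no override given"
            )
        vs = tuple(float(v) for v in voxel_size_nm)
    else:
        vs = tuple(float(s) / 10.0 for s in spacing_ang)
    mask = arr > 0
    if transpose:
        mask = mask.T  # -> (z, y, x)
    frame = SceneFrame(voxel_size_nm=vs, dims_voxels=tuple(int(n) for n in arr.shape))
    return mask, frame


def write_volume_mask(mask: np.ndarray, frame: SceneFrame, path) -> None:
    """Write a (z, y, x) boolean mask as an MRC volume (mode 2, 0/1)."""
    mask = np.asarray(mask, bool)
    grid = gemmi.FloatGrid(np.ascontiguousarray(mask.T.astype(np.float32)))
    ext_ang = frame.bounds_nm * 10.0  # nm -> Å
    grid.set_unit_cell(gemmi.UnitCell(ext_ang[0], ext_ang[1], ext_ang[2], 90, 90, 90))
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header()
    ccp4.write_ccp4_map(str(path))


def surface_points_from_mask(mask: np.ndarray, frame: SceneFrame) -> np.ndarray:
    """Centers (nm, (x, y, z)) of boundary voxels of a (z, y, x) mask.

    A boundary voxel is a true voxel with at least one false 6-neighbor
    (faces only). Raises :class:`ValidationError` on an empty mask.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValidationError("empty mask has no surface")
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    interior = ndimage.binary_erosion(mask, structure=structure, border_value=0)
    boundary = mask & ~interior
    idx_zyx = np.argwhere(boundary)  # (N, 3) as (iz, iy, ix)
    vs = np.asarray(frame.voxel_size_nm)  # (x, y, z)
    return idx_zyx[:, ::-1] * vs  # (x, y, z) nm, 0-based centers


# ---------------------------------------------------------------------------
# scene bundles
# ---------------------------------------------------------------------------

def write_scene(scene: Scene, directory) -> None:
    """Write a scene as a directory bundle with a JSON manifest."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "frame": {
            "voxel_size_nm": list(scene.frame.voxel_size_nm),
            "dims_voxels": list(scene.frame.dims_voxels),
            "tilt_axis": scene.frame.tilt_axis,
            "condition_label": scene.frame.condition_label,
        },
        "provenance": scene.provenance,
        "membranes": [],
        "organelles": [],
    }
    if scene.filaments:
        write_filament_table(scene.filaments, d / "filaments.csv")
        manifest["filaments"] = "filaments.csv"
    for m in scene.membranes:
        if m.plane is not None:
            manifest["membranes"].append({
                "role": m.role,
                "plane": {"point": list(m.plane[0]), "normal": list(m.plane[1])},
            })
        else:
            fname = f"membrane_{m.role}_points.csv"
            pd.DataFrame(m.surface_points, columns=["x", "y", "z"]).to_csv(
                d / fname, index=False)
            manifest["membranes"].append({"role": m.role, "surface_points": fname})
    for o in scene.organelles:
        if o.is_spheres:
            manifest["organelles"].append({
                "kind": o.kind,
                "spheres": {
                    "centers": [list(c) for c in o.centers],
                    "radii": list(o.radii),
                },
            })
        else:
            fname = f"organelles_{o.kind}.mrc"
            write_volume_mask(o.mask, o.frame, d / fname)
            manifest["organelles"].append({"kind": o.kind, "mask": fname})
    (d / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def read_scene(directory) -> Scene:
    """Read a scene bundle written by :func:`write_scene`."""
    d = Path(directory)
    manifest_path = d / "manifest.json"
    if not manifest_path.exists():
        raise FormatError(f"{d}: no manifest.json")
    manifest = json.loads(manifest_path.read_text())
    fr = manifest["frame"]
    frame = SceneFrame(
        voxel_size_nm=tuple(fr["voxel_size_nm"]),
        dims_voxels=tuple(fr["dims_voxels"]),
        tilt_axis=fr.get("tilt_axis", "y"),
        condition_label=fr.get("condition_label", ""),
    )
    filaments = []
    if "filaments" in manifest:
        filaments = read_filament_table(d / manifest["filaments"], frame, units="nm")
    membranes = []
    for entry in manifest.get("membranes", []):
        if "plane" in entry:
            membranes.append(MembraneModel.from_plane(
                entry["role"], entry["plane"]["point"], entry["plane"]["normal"]))
        else:
            pts = pd.read_csv(d / entry["surface_points"])[["x", "y", "z"]].to_numpy()
            membranes.append(MembraneModel.from_surface_points(entry["role"], pts))
    organelles = []
    for entry in manifest.get("organelles", []):
        if "spheres" in entry:
            organelles.append(OrganelleSet(
                kind=entry["kind"],
                centers=np.array(entry["spheres"]["centers"], float),
                radii=np.array(entry["spheres"]["radii"], float),
            ))
        else:
            mask, mframe = read_volume_mask(d / entry["mask"])
            organelles.append(OrganelleSet(kind=entry["kind"], mask=mask, frame=mframe))
    return Scene(frame=frame, filaments=filaments, membranes=membranes,
                 organelles=organelles, provenance=manifest.get("provenance", {}))
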