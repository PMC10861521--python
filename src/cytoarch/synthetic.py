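"""Synthetic cytoskeleton phantoms with known ground truth.

Generates scenes with the statistical structure the quantification modules
assume — in-plane parallel bundles at ~12.5 nm spacing, a free-filament
population with a controllable quasi-orthogonal (>= 45 deg) fraction,
ventral/dorsal membrane planes ~200 nm apart, ISG spheres with enforced
clearances, and microtubule polylines — plus rasterized fluorescence-like
images for the meshwork module. Every output is a pure function of
(recipe, seed): the recipe's seed feeds per-component child generators in a
fixed order.

Orientation sampling is a two-class mixture: with probability
``frac_quasi_orthogonal`` the chord elevation is uniform on [45, 90) deg,
otherwise uniform on [0, 45) deg; azimuths are uniform. Free filaments are
laid with their near endpoint close to the VM, and quasi-orthogonal
filaments point away from it (+z), so a high quasi-orthogonal fraction
produces the co-directed "blooming" anchored architecture while a low one
produces in-plane "netlike" crossings.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import GenerationError
from .model import Filament, MembraneModel, OrganelleSet, Scene, SceneFrame

_MAX_PLACEMENT_TRIES = 2000


@dataclass(frozen=True)
class SceneRecipe:
    """Parameters of one synthetic scene; identical recipe+seed => identical scene."""

    seed: int = 0
    bounds_nm: tuple[float, float, float] = (1000.0, 1000.0, 260.0)
    voxel_size_nm: float = 1.34
    vm_z_nm: float = 0.0
    dorsal_z_nm: float = 200.0
    condition_label: str = ""
    # bundles: in-plane parallel filaments at fixed lateral spacing
    n_bundles: int = 4
    filaments_per_bundle: int = 8
    bundle_spacing_nm: float = 12.5
    spacing_jitter_nm: float = 0.5
    # free filaments: orientation mixture
    n_free_filaments: int = 200
    frac_quasi_orthogonal: float = 0.03
    filament_length_nm: float = 60.0
    near_endpoint_z_range_nm: tuple[float, float] = (2.0, 66.0)
    # organelles
    n_isg: int = 5
    isg_radius_nm: tuple[float, float] = (100.0, 175.0)
    min_clearance_nm: float = 20.0
    isg_filament_clearance_nm: float = 0.0
    isg_z_range_nm: tuple[float, float] = (60.0, 250.0)
    # microtubules
    n_mt: int = 4
    mt_length_nm: float = 400.0

    def __post_init__(self):
        if not (0.0 <= self.frac_quasi_orthogonal <= 1.0):
            raise GenerationError("frac_quasi_orthogonal must be in [0, 1]")
        if self.vm_z_nm >= self.dorsal_z_nm:
            raise GenerationError("vm_z must lie below dorsal_z")
        for name in ("n_bundles", "filaments_per_bundle", "n_free_filaments",
                     "n_isg", "n_mt"):
            if getattr(self, name) < 0:
                raise GenerationError(f"{name} must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Per-filament truth emitted alongside each synthetic scene."""

    table: pd.DataFrame  # filament_id, class, true_orientation_deg,
    #                      quasi_orthogonal, anchored


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    seqs = np.random.SeedSequence(seed).spawn(n)
    return [np.random.default_rng(s) for s in seqs]


def _direction(elevation_deg: float, azimuth_deg: float) -> np.ndarray:
    e = np.radians(elevation_deg)
    a = np.radians(azimuth_deg)
    return np.array([
        np.cos(e) * np.cos(a), np.cos(e) * np.sin(a), np.sin(e)
    ])


def make_scene(recipe: SceneRecipe) -> tuple[Scene, GroundTruth]:
    """Build a scene plus its ground truth from a recipe, deterministically."""
    rng_bundle, rng_free, rng_isg, rng_mt = _child_rngs(recipe.seed, 4)
    bx, by, bz = recipe.bounds_nm
    filaments: list[Filament] = []
    truth_rows = []
    length = recipe.filament_length_nm

    # --- ISGs first: spheres with pairwise clearance; filaments are then
    # laid outside the ISG standoff, which is how the "ISGs nearer/farther
    # from actin" conditions are constructed
    centers: list[np.ndarray] = []
    radii: list[float] = []
    z_lo_isg, z_hi_isg = recipe.isg_z_range_nm
    for _ in range(recipe.n_isg):
        for _try in range(_MAX_PLACEMENT_TRIES):
            r = rng_isg.uniform(*recipe.isg_radius_nm)
            c = np.array([
                rng_isg.uniform(r, bx - r),
                rng_isg.uniform(r, by - r),
                rng_isg.uniform(z_lo_isg, z_hi_isg),
            ])
            if all(np.linalg.norm(c - c2) >= r + r2 + recipe.min_clearance_nm
                   for c2, r2 in zip(centers, radii)):
                centers.append(c)
                radii.append(r)
                break
        else:
            raise GenerationError(
                "could not place ISGs with the requested clearance")
    isg_centers = np.array(centers) if centers else np.empty((0, 3))
    isg_radii = np.array(radii)

    def clear_of_isgs(points: np.ndarray) -> bool:
        if len(isg_centers) == 0 or recipe.isg_filament_clearance_nm <= 0:
            return True
        d = (np.linalg.norm(points[:, None, :] - isg_centers[None, :, :],
                            axis=2) - isg_radii[None, :])
        return bool(d.min() >= recipe.isg_filament_clearance_nm)

    # --- bundles: parallel in-plane filaments stacked at fixed spacing
    for b in range(recipe.n_bundles):
        azimuth = rng_bundle.uniform(0.0, 360.0)
        direction = _direction(0.0, azimuth)
        lateral = _direction(0.0, azimuth + 90.0)
        margin = length + recipe.filaments_per_bundle * recipe.bundle_spacing_nm
        for _try in range(_MAX_PLACEMENT_TRIES):
            anchor = np.array([
                rng_bundle.uniform(margin, bx - margin),
                rng_bundle.uniform(margin, by - margin),
                rng_bundle.uniform(5.0, 60.0),
            ])
            starts = []
            for k in range(recipe.filaments_per_bundle):
                spacing = recipe.bundle_spacing_nm + rng_bundle.normal(
                    0.0, recipe.spacing_jitter_nm)
                offset = anchor + lateral * spacing * k
                if recipe.spacing_jitter_nm > 0:
                    offset = offset + lateral * rng_bundle.normal(
                        0.0, recipe.spacing_jitter_nm)
                starts.append(offset)
            endpoints = np.concatenate(
                [np.vstack([s, s + direction * length]) for s in starts])
            if clear_of_isgs(endpoints):
                break
        else:
            raise GenerationError("could not place a bundle clear of ISGs")
        for k, offset in enumerate(starts):
            fid = f"bundle{b}_f{k}"
            pts = np.vstack([offset, offset + direction * length])
            filaments.append(Filament(id=fid, kind="actin", points=pts))
            truth_rows.append((fid, "bundle", 0.0, False, True))

    # --- free filaments: orientation mixture, near endpoint close to the VM
    z_lo, z_hi = recipe.near_endpoint_z_range_nm
    for i in range(recipe.n_free_filaments):
        quasi = bool(rng_free.random() < recipe.frac_quasi_orthogonal)
        elevation = (rng_free.uniform(45.0, 90.0) if quasi
                     else rng_free.uniform(0.0, 45.0))
        azimuth = rng_free.uniform(0.0, 360.0)
        direction = _direction(elevation, azimuth)  # +z: points away from VM
        for _ in range(_MAX_PLACEMENT_TRIES):
            near = np.array([
                rng_free.uniform(length, bx - length),
                rng_free.uniform(length, by - length),
                rng_free.uniform(z_lo, z_hi),
            ])
            far = near + direction * length
            if 0.0 <= far[2] <= bz and clear_of_isgs(np.vstack([near, far])):
                break
        else:
            raise GenerationError("could not place a free filament in bounds")
        fid = f"free{i}"
        filaments.append(Filament(
            id=fid, kind="actin", points=np.vstack([near, far])))
        anchored = bool(near[2] - recipe.vm_z_nm <= 60.0)
        truth_rows.append((fid, "free", float(elevation), quasi, anchored))

    # --- microtubules: long gently tilted polylines
    for i in range(recipe.n_mt):
        azimuth = rng_mt.uniform(0.0, 360.0)
        elevation = rng_mt.uniform(0.0, 10.0)
        direction = _direction(elevation, azimuth)
        margin = recipe.mt_length_nm
        start = np.array([
            rng_mt.uniform(margin, bx - margin) if bx > 2 * margin else bx / 2,
            rng_mt.uniform(margin, by - margin) if by > 2 * margin else by / 2,
            rng_mt.uniform(30.0, max(31.0, bz - 60.0)),
        ])
        # 3-point polyline (start, mid, end) to exercise resampling
        mid = start + direction * (recipe.mt_length_nm / 2)
        end = start + direction * recipe.mt_length_nm
        filaments.append(Filament(
            id=f"mt{i}", kind="mt", points=np.vstack([start, mid, end])))

    frame = SceneFrame(
        voxel_size_nm=(recipe.voxel_size_nm,) * 3,
        dims_voxels=tuple(int(np.ceil(b / recipe.voxel_size_nm))
                          for b in recipe.bounds_nm),
        condition_label=recipe.condition_label,
    )
    membranes = [
        MembraneModel.xy_plane("vm", recipe.vm_z_nm),
        MembraneModel.xy_plane("dorsal", recipe.dorsal_z_nm),
    ]
    organelles = []
    if centers:
        organelles.append(OrganelleSet(
            kind="isg", centers=np.array(centers), radii=np.array(radii)))
    scene = Scene(
        frame=frame, filaments=filaments, membranes=membranes,
        organelles=organelles,
        provenance={"generator": "cytoarch.synthetic", "seed": recipe.seed},
    )
    truth = GroundTruth(table=pd.DataFrame(truth_rows, columns=[
        "filament_id", "class", "true_orientation_deg",
        "quasi_orthogonal", "anchored",
    ]))
    return scene, truth


def basal_recipe(seed: int = 0, **overrides) -> SceneRecipe:
    """Resting-state preset: almost all in-plane, netlike, ISGs close to actin."""
    return replace(SceneRecipe(
        seed=seed, condition_label="basal",
        frac_quasi_orthogonal=0.03,
        isg_filament_clearance_nm=0.0,
    ), **overrides)


def stimulated_recipe(seed: int = 0, **overrides) -> SceneRecipe:
    """Post-remodeling preset: more quasi-orthogonal co-directed ("blooming")
    filaments and ISGs held farther from actin."""
    return replace(SceneRecipe(
        seed=seed, condition_label="stimulated",
        frac_quasi_orthogonal=0.15,
        n_bundles=3,
        isg_filament_clearance_nm=60.0,
    ), **overrides)


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def render_masks(
    scene: Scene, voxel_size_nm: float
) -> tuple[dict[str, np.ndarray], SceneFrame]:
    """Voxelize organelle spheres and membrane slabs (center-inside test).

    Returns ``({"isg": ..., "vm": ..., "dorsal": ...}, frame)`` with
    (z, y, x) boolean arrays; absent components give all-false masks.
    """
    import warnings

    if voxel_size_nm <= 0:
        raise GenerationError("voxel size must be positive")
    bounds = np.asarray(scene.frame.bounds_nm)
    dims_xyz = np.maximum(np.ceil(bounds / voxel_size_nm).astype(int), 1)
    frame = SceneFrame(
        voxel_size_nm=(voxel_size_nm,) * 3,
        dims_voxels=tuple(int(d) for d in dims_xyz),
        condition_label=scene.frame.condition_label,
    )
    shape_zyx = tuple(dims_xyz[::-1])
    zz, yy, xx = np.meshgrid(
        *[np.arange(n) * voxel_size_nm for n in shape_zyx], indexing="ij")
    masks = {k: np.zeros(shape_zyx, bool) for k in ("isg", "vm", "dorsal")}
    isg = scene.organelle_set("isg")
    if isg is not None and isg.is_spheres:
        if np.min(isg.radii) < voxel_size_nm:
            warnings.warn("voxel size exceeds smallest organelle radius "
                          "(aliasing)", stacklevel=2)
        for c, r in zip(isg.centers, isg.radii):
            d2 = (xx - c[0]) ** 2 + (yy - c[1]) ** 2 + (zz - c[2]) ** 2
            masks["isg"] |= d2 <= r * r
    for role in ("vm", "dorsal"):
        m = scene.membrane(role)
        if m is not None and m.plane is not None:
            p0, n = m.plane
            dist = (xx - p0[0]) * n[0] + (yy - p0[1]) * n[1] + (zz - p0[2]) * n[2]
            masks[role] |= np.abs(dist) <= voxel_size_nm / 2.0
    return masks, frame


def render_image(
    lines: list[tuple[tuple[float, float], tuple[float, float]]],
    shape: tuple[int, int],
    pixel_size_nm: float,
    psf_sigma_nm: float = 0.0,
    noise_model: str | None = None,
    noise_scale: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize 2D line segments into a fluorescence-like image.

    ``lines`` are ((r0, c0), (r1, c1)) endpoints in nm. Segments are drawn
    as unit-intensity 1-pixel strokes (the ground-truth skeleton), blurred
    with a Gaussian PSF of ``psf_sigma_nm``, and noised (``"gaussian"``:
    additive sd = noise_scale; ``"poisson"``: counts at
    ``noise_scale`` photons per unit intensity) deterministically under
    ``seed``. Returns ``(image, true_skeleton)``.
    """
    from skimage.draw import line as draw_line

    if psf_sigma_nm < 0:
        raise GenerationError("psf sigma must be >= 0")
    skeleton = np.zeros(shape, bool)
    for (a, b) in lines:
        r0, c0 = (int(round(a[0] / pixel_size_nm)),
                  int(round(a[1] / pixel_size_nm)))
        r1, c1 = (int(round(b[0] / pixel_size_nm)),
                  int(round(b[1] / pixel_size_nm)))
        rr, cc = draw_line(r0, c0, r1, c1)
        keep = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
        skeleton[rr[keep], cc[keep]] = True
    image = skeleton.astype(float)
    if psf_sigma_nm > 0:
        image = ndimage.gaussian_filter(image, psf_sigma_nm / pixel_size_nm)
    rng = np.random.default_rng(seed)
    if noise_model == "gaussian":
        image = image + rng.normal(0.0, noise_scale, size=image.shape)
    elif noise_model == "poisson":
        image = rng.poisson(np.clip(image, 0, None) * noise_scale).astype(float)
    elif noise_model is not None:
        raise GenerationError(f"unknown noise model {noise_model!r}")
    return image, skeleton
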