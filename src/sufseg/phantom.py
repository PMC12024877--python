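"""Parametric skull phantoms and simulated bone defects.

Real cranio-maxillofacial CT is replaced by a closed-shell phantom: an
ellipsoidal calvarium fused with a smaller facial/mandibular shell, carrying
seven named anatomical zones so that defects can be placed per region.
Defects are carved the way the emulated corpus was built: by subtracting
unions of randomly deformed spheres from the bone, with complexity tiers
controlling sphere count and deformation amplitude.

All sizes are physical (mm); all randomness flows from integer seeds through
``numpy.random.Generator`` so every artefact is bit-reproducible.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .volume import Volume

__all__ = [
    "REGIONS",
    "LATERALITIES",
    "COMPLEXITIES",
    "REGION_TABLE_LABELS",
    "PlacementError",
    "generate_skull_phantom",
    "deformed_sphere_mask",
    "carve_defect",
    "mask_max_extent_mm",
]

#: Canonical region categories (row labels of the evaluation table).
REGIONS = (
    "anterior-skull-and-forehead",
    "zygomatic-arch",
    "zygomatic-bone",
    "NOE",
    "maxillary-sinus-wall",
    "mandibular-body",
    "mandibular-ramus-and-condyle",
)

#: Human-readable labels used in emitted reports.
REGION_TABLE_LABELS = {
    "anterior-skull-and-forehead": "Anterior skull and forehead",
    "zygomatic-arch": "Zygomatic arch",
    "zygomatic-bone": "Zygomatic bone",
    "NOE": "NOE Region",
    "maxillary-sinus-wall": "Wall of maxillary sinus",
    "mandibular-body": "Mandibular body",
    "mandibular-ramus-and-condyle": "Mandibular ramus and condylar",
}

LATERALITIES = ("left", "right", "bilateral")
COMPLEXITIES = ("simple", "moderate", "complex")

#: Defect maximum-diameter envelope in mm.
SIZE_RANGE_MM = (15.0, 45.0)

# Sphere count and angular deformation amplitude per complexity tier:
# simple -> smooth convex, complex -> highly irregular, multiple concavities.
_COMPLEXITY_PARAMS = {
    "simple": dict(n_spheres=(1, 1), amplitude=(0.02, 0.12), n_lobes=2),
    "moderate": dict(n_spheres=(2, 3), amplitude=(0.15, 0.30), n_lobes=3),
    "complex": dict(n_spheres=(4, 5), amplitude=(0.30, 0.45), n_lobes=4),
}


class PlacementError(ValueError):
    """Raised when a defect cannot be placed in the requested region."""


def _grid_coords_mm(shape, spacing):
    """Per-axis physical coordinate vectors (mm) of voxel centres."""
    return [np.arange(n) * s for n, s in zip(shape, spacing)]


def generate_skull_phantom(
    seed: int,
    grid_shape: tuple[int, int, int] = (64, 64, 64),
    spacing_mm: float = 1.0,
) -> Volume:
    """Build a binary closed-shell skull phantom with 7 anatomical zones.

    Axis 0 runs front-to-back, axis 1 left-to-right (midline = centre plane),
    axis 2 bottom-to-top.  The zone label map (0 = unzoned bone/background,
    1..7 = :data:`REGIONS` order) is stored in ``meta["zones"]``.

    Parameters
    ----------
    seed
        Controls small random jitter of the shell axes, so phantoms differ
        between seeds but are bit-identical for equal seeds.
    grid_shape
        Voxel grid, every component >= 16.
    spacing_mm
        Isotropic voxel size in mm.
    """
    grid_shape = tuple(int(n) for n in grid_shape)
    if len(grid_shape) != 3 or min(grid_shape) < 16:
        raise ValueError(
            f"grid_shape components must be >= 16 to contain a >=2-voxel shell, got {grid_shape}"
        )
    if spacing_mm <= 0:
        raise ValueError("spacing_mm must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5C011]))
    spacing = (spacing_mm,) * 3
    extent = np.array(grid_shape, dtype=float) * spacing_mm

    ys, xs, zs = np.meshgrid(*_grid_coords_mm(grid_shape, spacing), indexing="ij")
    jit = 1.0 + 0.03 * rng.uniform(-1, 1, size=6)

    thickness = max(2.05 * spacing_mm, 0.045 * extent.min())

    def shell(center_frac, semi_frac, jitter):
        c = center_frac * extent
        a_out = semi_frac * extent * jitter
        a_in = np.maximum(a_out - thickness, 0.3 * a_out)
        r_out = ((ys - c[0]) / a_out[0]) ** 2 + ((xs - c[1]) / a_out[1]) ** 2 + (
            (zs - c[2]) / a_out[2]
        ) ** 2
        r_in = ((ys - c[0]) / a_in[0]) ** 2 + ((xs - c[1]) / a_in[1]) ** 2 + (
            (zs - c[2]) / a_in[2]
        ) ** 2
        return (r_out <= 1.0) & (r_in > 1.0)

    # Calvarium: large upper shell.  Facial/mandibular block: smaller
    # lower-front shell, clipped to its front-lower half so a jaw-like arc
    # remains.
    calvarium = shell(np.array([0.50, 0.50, 0.62]), np.array([0.40, 0.36, 0.33]), jit[:3])
    face = shell(np.array([0.40, 0.50, 0.34]), np.array([0.26, 0.27, 0.28]), jit[3:])
    face &= ys <= 0.62 * extent[0]
    face &= zs <= 0.58 * extent[2]
    skull = calvarium | face

    # Anatomical zone assignment in normalized coordinates.
    yn = ys / extent[0]          # 0 = front
    xn = xs / extent[1] - 0.5    # signed lateral offset, 0 = midline
    zn = zs / extent[2]          # 0 = bottom
    ax = np.abs(xn)

    zones = np.zeros(grid_shape, dtype=np.uint8)
    mand = skull & (zn < 0.26)
    zones[mand & (yn < 0.45) & (ax < 0.22)] = 6          # mandibular-body
    zones[mand & ((yn >= 0.45) | (ax >= 0.22))] = 7      # ramus and condyle
    mid = skull & (zn >= 0.26) & (zn < 0.52) & (zones == 0)
    zones[mid & (yn < 0.42) & (ax < 0.10)] = 4           # NOE
    zones[mid & (yn < 0.42) & (ax >= 0.10) & (ax < 0.24)] = 3   # zygomatic bone
    zones[mid & (yn < 0.65) & (ax >= 0.24)] = 2          # zygomatic arch
    zones[mid & (yn >= 0.42) & (yn < 0.62) & (ax < 0.24) & (zones == 0)] = 5  # maxillary sinus wall
    upper = skull & (zn >= 0.52) & (yn < 0.48)
    zones[upper] = 1                                     # anterior skull / forehead

    vol = Volume(skull.astype(np.uint8), spacing)
    vol.meta["zones"] = zones
    vol.meta["zone_names"] = dict(enumerate(REGIONS, start=1))
    return vol


def deformed_sphere_mask(
    center: tuple[int, int, int],
    radius_mm: float,
    deform_amplitude: float,
    n_lobes: int,
    seed: int,
    grid: Volume,
) -> Volume:
    """Binary mask of a sphere whose radius is angularly modulated.

    The modulation field is a sum of ``n_lobes`` smooth directional bumps
    (von Mises-Fisher kernels at random orientations), normalized to
    [-1, 1] and scaled by ``deform_amplitude``; amplitude 0 (or 0 lobes)
    yields the exact discretized sphere.
    """
    if radius_mm <= 0:
        raise ValueError("radius_mm must be > 0")
    if not (0 <= deform_amplitude < 1):
        raise ValueError("deform_amplitude must lie in [0, 1)")
    center = tuple(int(c) for c in center)
    shape = grid.shape
    if any(c < 0 or c >= n for c, n in zip(center, shape)):
        raise ValueError(f"center {center} lies outside grid of shape {shape}")

    spacing = np.asarray(grid.spacing)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xD5BA11]))
    # Random lobe orientations and signs are always drawn so the RNG stream,
    # and hence any surrounding sampling, is amplitude-independent.
    dirs = rng.normal(size=(max(n_lobes, 1), 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    coefs = rng.uniform(-1.0, 1.0, size=max(n_lobes, 1))

    r_max = radius_mm * (1.0 + deform_amplitude) + spacing.max()
    lo = [max(0, int(np.floor(c - r_max / s))) for c, s in zip(center, spacing)]
    hi = [min(n, int(np.ceil(c + r_max / s)) + 1) for c, n, s in zip(center, shape, spacing)]

    axes = [
        (np.arange(l, h) - c) * s for l, h, c, s in zip(lo, hi, center, spacing)
    ]
    dy, dx, dz = np.meshgrid(*axes, indexing="ij")
    dist = np.sqrt(dy**2 + dx**2 + dz**2)

    if deform_amplitude > 0 and n_lobes > 0:
        with np.errstate(invalid="ignore", divide="ignore"):
            uy, ux, uz = dy / dist, dx / dist, dz / dist
        g = np.zeros_like(dist)
        kappa = 4.0
        for (vy, vx, vz), c in zip(dirs[:n_lobes], coefs[:n_lobes]):
            cosang = uy * vy + ux * vx + uz * vz
            g += c * np.exp(kappa * (cosang - 1.0))
        g = np.nan_to_num(g, nan=0.0)
        gmax = np.abs(g).max()
        if gmax > 0:
            g /= gmax
        r_local = radius_mm * (1.0 + deform_amplitude * g)
    else:
        r_local = radius_mm

    sub = dist <= r_local
    mask = np.zeros(shape, dtype=np.uint8)
    mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = sub
    return Volume(mask, grid.spacing, grid.origin)


def mask_max_extent_mm(mask: np.ndarray, spacing) -> float:
    """Maximum pairwise (Euclidean, mm) distance between mask voxel centres.

    Exact: the diameter of a point set is attained on its convex hull; for
    small sets the all-pairs computation is used directly.
    """
    pts = np.argwhere(mask) * np.asarray(spacing, dtype=float)
    n = len(pts)
    if n == 0:
        return 0.0
    if n == 1:
        return 0.0
    if n > 400:
        try:
            hull = ConvexHull(pts, qhull_options="QJ")
            pts = pts[hull.vertices]
        except QhullError:
            pass
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


def _midline(width: int) -> float:
    """Midsagittal plane as a (possibly fractional) axis-1 index."""
    return (width - 1) / 2.0


def _laterality_ok(mask: np.ndarray, laterality: str) -> bool:
    xs = np.argwhere(mask)[:, 1]
    mid = _midline(mask.shape[1])
    if laterality == "left":
        return not np.any(xs > mid)
    if laterality == "right":
        return not np.any(xs < mid)
    return bool(np.any(xs < mid) and np.any(xs > mid))


def carve_defect(
    skull: Volume,
    region: str,
    laterality: str,
    complexity: str,
    target_diameter_mm: float,
    seed: int,
) -> tuple[Volume, Volume]:
    """Subtract a union of deformed spheres from the skull in one region.

    Returns ``(defective_skull, defect_mask)`` with the exact partition
    property ``defective | mask == skull`` and ``defective & mask == 0``.
    Left/right defects never cross the midsagittal plane (enforced by
    clipping); bilateral defects are placed on the midline within the
    region's band and must end up with bone on both sides.

    The final mask is clipped to a ball of diameter 45 mm and grown until
    its maximum extent reaches 15 mm, so every emitted defect respects the
    size envelope.
    """
    if region not in REGIONS:
        raise ValueError(f"unknown region {region!r}")
    if laterality not in LATERALITIES:
        raise ValueError(f"unknown laterality {laterality!r}")
    if complexity not in COMPLEXITIES:
        raise ValueError(f"unknown complexity {complexity!r}")
    if not skull.is_binary():
        raise ValueError("skull volume must be binary")
    zones = skull.meta.get("zones")
    if zones is None:
        raise PlacementError("skull phantom carries no zone metadata")
    region_id = REGIONS.index(region) + 1
    zone_vox = np.argwhere(zones == region_id)
    if len(zone_vox) == 0:
        raise PlacementError(f"region zone {region!r} is empty in this phantom")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xCA54E]))
    spacing = np.asarray(skull.spacing)
    mid = _midline(skull.shape[1])
    skull_bool = skull.data.astype(bool)

    # --- choose the defect centre -------------------------------------
    if laterality == "bilateral":
        # Bone voxel on/next to the midline, closest (in the front-height
        # plane) to the zone centroid: the defect genuinely crosses midline.
        cand = np.argwhere(skull_bool & (np.abs(np.arange(skull.shape[1])[None, :, None] - mid) <= 1.0))
        if len(cand) == 0:
            raise PlacementError("phantom has no bone on the midline")
        cz = zone_vox.mean(axis=0)
        d = ((cand[:, 0] - cz[0]) * spacing[0]) ** 2 + ((cand[:, 2] - cz[2]) * spacing[2]) ** 2
        center = tuple(cand[np.argmin(d)])
    else:
        side = zone_vox[:, 1] < mid if laterality == "left" else zone_vox[:, 1] > mid
        cand = zone_vox[side]
        if len(cand) == 0:
            raise PlacementError(f"region {region!r} has no voxels on the {laterality} side")
        # Prefer centres well away from the midline so clipping keeps extent.
        off = np.abs(cand[:, 1] - mid) * spacing[1]
        far = cand[off >= min(off.max(), 6.0)]
        center = tuple(far[rng.integers(len(far))])

    lo_mm, hi_mm = SIZE_RANGE_MM
    target = float(np.clip(target_diameter_mm, lo_mm, hi_mm))
    params = _COMPLEXITY_PARAMS[complexity]
    n_sph = int(rng.integers(params["n_spheres"][0], params["n_spheres"][1] + 1))
    amp = float(rng.uniform(*params["amplitude"]))
    lobes = params["n_lobes"]

    # Satellite sphere offsets/radii, fixed once; only the scale grows below.
    sat = [
        (rng.normal(size=3), rng.uniform(0.35, 0.6), rng.uniform(0.35, 0.75))
        for _ in range(n_sph - 1)
    ]
    sph_seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=n_sph)]

    def build(scale: float) -> np.ndarray:
        r0 = scale * target / 2.0
        union = deformed_sphere_mask(center, r0, amp, lobes, sph_seeds[0], skull).data.astype(bool)
        for (direction, rfrac, ofrac), s in zip(sat, sph_seeds[1:]):
            d = direction / np.linalg.norm(direction)
            c = np.asarray(center) + d * (ofrac * r0) / spacing
            c = np.clip(np.round(c).astype(int), 0, np.asarray(skull.shape) - 1)
            union |= deformed_sphere_mask(
                tuple(c), rfrac * r0, amp, lobes, s, skull
            ).data.astype(bool)
        mask = union & skull_bool
        # Laterality constraints.
        xs_idx = np.arange(skull.shape[1])[None, :, None]
        if laterality == "left":
            mask &= xs_idx <= mid
        elif laterality == "right":
            mask &= xs_idx >= mid
        # Hard 45 mm cap: clip to a ball around the primary centre.
        if mask.any():
            idx = np.argwhere(mask)
            d2 = (((idx - np.asarray(center)) * spacing) ** 2).sum(axis=1)
            keep = d2 <= (hi_mm / 2.0) ** 2
            mask = np.zeros_like(mask)
            mask[tuple(idx[keep].T)] = True
        return mask

    scale = 1.0
    mask = build(scale)
    for _ in range(10):
        if mask.any() and mask_max_extent_mm(mask, spacing) >= lo_mm:
            break
        scale *= 1.25
        mask = build(scale)
    if not mask.any():
        raise PlacementError(f"could not carve a non-empty defect in region {region!r}")
    extent = mask_max_extent_mm(mask, spacing)
    if extent < lo_mm:
        raise PlacementError(
            f"defect extent {extent:.1f} mm below {lo_mm} mm even after growth; grid too small"
        )
    if laterality == "bilateral" and not _laterality_ok(mask, "bilateral"):
        raise PlacementError("bilateral defect failed to cross the midline")

    defect = Volume(mask.astype(np.uint8), skull.spacing, skull.origin)
    defective = Volume(
        (skull_bool & ~mask).astype(np.uint8), skull.spacing, skull.origin, dict(skull.meta)
    )
    defect.meta["max_diameter_mm"] = extent
    defect.meta["volume_mm3"] = float(mask.sum()) * skull.voxel_volume_mm3
    return defective, defect
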