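"""Contour-to-mask conversion and margin/crop/ring constructions.

Rasterisation uses the even-odd rule on voxel centres, with optional
in-plane supersampling for partial-voxel refinement; margins use the exact
Euclidean distance transform with anisotropic spacing.
"""

from __future__ import annotations

import logging
import math

import numpy as np
from scipy import ndimage
from shapely import contains_xy
from shapely.geometry import Polygon

from .core import BinaryMask, ImageGrid3D, Structure

log = logging.getLogger(__name__)

__all__ = [
    "rasterize_structure",
    "expand_mask",
    "crop_target",
    "ring_region",
    "polygon_area_mm2",
]

#: Tolerance (mm) added to distance comparisons so voxels exactly on a
#: margin boundary are included.
_DIST_EPS = 1e-9


def polygon_area_mm2(vertices: np.ndarray) -> float:
    """Area of a closed planar polygon (shoelace via shapely)."""
    return Polygon(np.asarray(vertices, dtype=float)).area


def _slice_inside(
    polys: list[np.ndarray],
    xs: np.ndarray,
    ys: np.ndarray,
) -> np.ndarray:
    """Even-odd containment of the points (xs, ys) in a set of polygons.

    Containment parity across polygons defines the interior, so nested
    contours form holes.
    """
    inside = np.zeros(xs.shape, dtype=bool)
    for p in polys:
        poly = Polygon(p)
        if not poly.is_valid:
            poly = poly.buffer(0)
            if poly.is_empty:
                continue
        inside ^= contains_xy(poly, xs, ys)
    return inside


def rasterize_structure(
    structure: Structure,
    grid: ImageGrid3D,
    supersampling: int = 2,
) -> BinaryMask:
    """Voxelise a contour stack onto ``grid``.

    A voxel is occupied iff its centre lies inside the slice polygon
    (even-odd rule).  With ``supersampling`` f > 1, each voxel is judged by
    the majority of an f x f lattice of in-plane sub-centres (exact
    half-coverage ties decided by the voxel centre), which stabilises
    small-volume metrics on coarse grids.  Contours are assigned
    to the nearest grid slice within half a slice spacing; slices further
    out are dropped with a warning.
    """
    if supersampling < 1:
        raise ValueError("supersampling factor must be >= 1")
    occ = np.zeros(grid.shape, dtype=bool)
    warnings: list[str] = []

    if not structure.contours:
        warnings.append(f"structure {structure.name!r} has no contours; empty mask")
        log.warning(warnings[-1])
        return BinaryMask(grid, occ, warnings)

    f = int(supersampling)
    xs1 = grid.axis_coords(0)
    ys1 = grid.axis_coords(1)
    if f == 1:
        sub_x, sub_y = xs1, ys1
    else:
        # f sub-centres per voxel, symmetric about the voxel centre
        off = (np.arange(f) + 0.5) / f - 0.5
        sub_x = (xs1[:, None] + off[None, :] * grid.spacing[0]).ravel()
        sub_y = (ys1[:, None] + off[None, :] * grid.spacing[1]).ravel()
    gx, gy = np.meshgrid(sub_x, sub_y, indexing="ij")

    zs = grid.axis_coords(2)
    half_dz = grid.spacing[2] / 2.0
    dropped = 0
    for z, polys in structure.contours:
        k = int(round((z - grid.origin[2]) / grid.spacing[2]))
        if k < 0 or k >= grid.shape[2] or abs(z - zs[min(max(k, 0), len(zs) - 1)]) > half_dz + _DIST_EPS:
            dropped += 1
            continue
        inside = _slice_inside(polys, gx, gy)
        if f == 1:
            occ[:, :, k] |= inside
        else:
            cnt = inside.reshape(len(xs1), f, len(ys1), f).sum(axis=(1, 3))
            vox_in = cnt * 2 > f * f
            # exact half-coverage ties fall back to the voxel-centre rule,
            # which keeps the majority rule unbiased along straight edges
            ties = cnt * 2 == f * f
            if ties.any():
                gcx, gcy = np.meshgrid(xs1, ys1, indexing="ij")
                center_in = _slice_inside(polys, gcx[ties], gcy[ties])
                vox_in[ties] = center_in
            occ[:, :, k] |= vox_in
    if dropped:
        warnings.append(
            f"structure {structure.name!r}: {dropped} contour slice(s) outside "
            f"the grid z-range were dropped"
        )
        log.warning(warnings[-1])
    if not occ.any():
        warnings.append(f"structure {structure.name!r} rasterised to an empty mask")
        log.warning(warnings[-1])
    return BinaryMask(grid, occ, warnings)


def expand_mask(mask: BinaryMask, margin_mm: float) -> BinaryMask:
    """Isotropic Euclidean expansion: occupied voxels plus every voxel whose
    centre lies within ``margin_mm`` of an occupied voxel centre.

    Anisotropic voxel spacing is respected via the sampled distance
    transform; margin 0 is the identity.
    """
    if margin_mm < 0:
        raise ValueError("margin_mm must be >= 0")
    if margin_mm == 0 or not mask.occupancy.any():
        return BinaryMask(mask.grid, mask.occupancy.copy())
    dist = ndimage.distance_transform_edt(
        ~mask.occupancy, sampling=mask.grid.spacing
    )
    return BinaryMask(mask.grid, dist <= margin_mm + _DIST_EPS)


def crop_target(
    target_mask: BinaryMask,
    oar_masks: list[BinaryMask],
    crop_margin_mm: float = 3.0,
) -> BinaryMask:
    """Optimisation target: the target cropped ``crop_margin_mm`` away from
    the union of the organs at risk.

    Returns ``target - expand(union(oars), margin)``.  An empty result is
    flagged in the mask's warnings (the surrogate planner then refuses to
    plan).
    """
    out = target_mask.occupancy.copy()
    if oar_masks:
        union = np.zeros(target_mask.grid.shape, dtype=bool)
        for m in oar_masks:
            if m.grid != target_mask.grid:
                raise ValueError("all masks must share the target grid")
            union |= m.occupancy
        forbidden = expand_mask(
            BinaryMask(target_mask.grid, union), crop_margin_mm
        ).occupancy
        out &= ~forbidden
    warnings: list[str] = []
    if not out.any():
        warnings.append("cropped optimisation target is empty")
        log.warning(warnings[-1])
    return BinaryMask(target_mask.grid, out, warnings)


def ring_region(target_mask: BinaryMask, ring_radius_mm: float = 30.0) -> BinaryMask:
    """Shell of ``ring_radius_mm`` around the target, excluding the target.

    Used as an optional restriction of organ masks before metric
    evaluation, mirroring reporting of organ volume within 3 cm of the
    target.
    """
    if ring_radius_mm < 0:
        raise ValueError("ring_radius_mm must be >= 0")
    expanded = expand_mask(target_mask, ring_radius_mm)
    return BinaryMask(
        target_mask.grid, expanded.occupancy & ~target_mask.occupancy
    )


def mask_centroid_mm(mask: BinaryMask) -> np.ndarray:
    """Centre of mass of occupied voxels in patient coordinates (mm)."""
    idx = np.argwhere(mask.occupancy)
    if idx.size == 0:
        raise ValueError("cannot take centroid of an empty mask")
    return mask.grid.index_to_world(idx.mean(axis=0))[0]


def min_surface_distance_mm(a: BinaryMask, b: BinaryMask) -> float:
    """Minimum centre-to-region distance from mask ``a``'s voxels to mask
    ``b`` (0 when they overlap)."""
    if a.grid != b.grid:
        raise ValueError("masks must share a grid")
    if not a.occupancy.any() or not b.occupancy.any():
        return math.inf
    dist_to_b = ndimage.distance_transform_edt(
        ~b.occupancy, sampling=b.grid.spacing
    )
    return float(dist_to_b[a.occupancy].min())
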