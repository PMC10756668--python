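"""Dose sampling and dose-volume-histogram metrics.

All cohort results rest on two scalar metrics computed here:

* ``v_at_dose`` — absolute volume (cc) of a structure receiving at least a
  dose threshold (V33Gy is ``v_at_dose(..., 33.0)``);
* ``d_at_volume`` — minimum dose to the hottest x cc (D0.035cc is
  ``d_at_volume(..., 0.035)``).

Metrics are computed from the voxel dose list of the structure, never from
a binned curve, so DVH bin width affects plots only.  The dose threshold is
inclusive (>=) by default; a strict (>) mode is available and recorded in
reports.  At floating-point dose values the difference affects only exact
ties.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .core import BinaryMask, DoseGrid, ImageGrid3D

__all__ = [
    "DVHCurve",
    "sample_dose",
    "organ_doses",
    "v_at_dose",
    "d_at_volume",
    "cumulative_dvh",
    "coverage",
]


@dataclass
class DVHCurve:
    """Cumulative DVH: volume (cc) receiving at least each dose level."""

    bin_edges: np.ndarray  # increasing dose values, Gy (left edges)
    cumulative_volume: np.ndarray  # cc at each left edge

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.cumulative_volume = np.asarray(self.cumulative_volume, dtype=float)
        if self.bin_edges.shape != self.cumulative_volume.shape:
            raise ValueError("bin_edges and cumulative_volume differ in length")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        if np.any(np.diff(self.cumulative_volume) > 1e-12):
            raise ValueError("cumulative volume must be non-increasing")

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {"dose_gy": self.bin_edges, "volume_cc": self.cumulative_volume}
        )


def _interpolator(dose: DoseGrid, fill: float | None = None) -> RegularGridInterpolator:
    axes = [dose.grid.axis_coords(i) for i in range(3)]
    return RegularGridInterpolator(
        axes,
        dose.dose,
        method="linear",
        bounds_error=fill is None,
        fill_value=fill,
    )


def sample_dose(
    dose: DoseGrid, points: np.ndarray, out_of_bounds: str = "error"
) -> np.ndarray:
    """Trilinear interpolation of the dose field at mm patient coordinates.

    ``out_of_bounds``: ``"error"`` (default) raises on any point outside the
    voxel-centre hull; ``"clamp"`` clamps to the nearest edge value.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if out_of_bounds not in ("error", "clamp"):
        raise ValueError("out_of_bounds must be 'error' or 'clamp'")
    if out_of_bounds == "clamp":
        lo = np.asarray([ax[0] for ax in (dose.grid.axis_coords(i) for i in range(3))])
        hi = np.asarray(
            [dose.grid.axis_coords(i)[-1] for i in range(3)]
        )
        pts = np.clip(pts, lo, hi)
        return _interpolator(dose)(pts)
    try:
        return _interpolator(dose)(pts)
    except ValueError as exc:
        inside = dose.grid.contains(pts)
        bad = pts[~inside]
        offender = bad[0] if len(bad) else pts[0]
        raise ValueError(
            f"point {tuple(offender)} lies outside the dose grid"
        ) from exc


def _resample_to(dose: DoseGrid, grid: ImageGrid3D) -> np.ndarray:
    """Dose values at the voxel centres of ``grid`` (trilinear, clamped)."""
    if dose.grid == grid:
        return dose.dose
    ax = [grid.axis_coords(i) for i in range(3)]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    vals = sample_dose(dose, pts, out_of_bounds="clamp")
    return vals.reshape(grid.shape)


def organ_doses(
    dose: DoseGrid,
    organ_mask: BinaryMask,
    restrict_mask: BinaryMask | None = None,
) -> np.ndarray:
    """Voxel dose list of an organ (optionally restricted), on the mask grid.

    The dose field is resampled to the mask grid by trilinear interpolation
    when the grids differ.
    """
    occ = organ_mask.occupancy
    if restrict_mask is not None:
        if restrict_mask.grid != organ_mask.grid:
            raise ValueError("restrict_mask must share the organ mask grid")
        occ = occ & restrict_mask.occupancy
    field = _resample_to(dose, organ_mask.grid)
    return field[occ]


def v_at_dose(
    dose: DoseGrid,
    organ_mask: BinaryMask,
    dose_threshold_gy: float,
    restrict_mask: BinaryMask | None = None,
    strict: bool = False,
) -> float:
    """Absolute volume (cc) of the organ receiving at least the threshold.

    ``strict=True`` counts voxels with dose strictly greater than the
    threshold instead.
    """
    if dose_threshold_gy < 0:
        raise ValueError("dose threshold must be >= 0")
    doses = organ_doses(dose, organ_mask, restrict_mask)
    if doses.size == 0:
        return 0.0
    n = (doses > dose_threshold_gy).sum() if strict else (doses >= dose_threshold_gy).sum()
    return float(n) * organ_mask.grid.voxel_volume_cc


def d_at_volume(
    dose: DoseGrid,
    organ_mask: BinaryMask,
    volume_cc: float,
    restrict_mask: BinaryMask | None = None,
) -> float:
    """Minimum dose (Gy) received by the hottest ``volume_cc`` of the organ.

    Defined as the minimum voxel dose d such that the volume receiving
    >= d is at most ``volume_cc``; computed from the sorted voxel doses.
    """
    doses = organ_doses(dose, organ_mask, restrict_mask)
    vox_cc = organ_mask.grid.voxel_volume_cc
    total = doses.size * vox_cc
    if volume_cc <= 0:
        raise ValueError("volume_cc must be > 0")
    if doses.size == 0 or volume_cc > total + 1e-12:
        raise ValueError(
            f"requested volume {volume_cc} cc exceeds organ volume {total:.4f} cc"
        )
    k = int(np.floor(volume_cc / vox_cc + 1e-12))  # max voxel count allowed
    if k >= doses.size:
        return float(doses.min())
    asc = np.sort(doses)
    n = asc.size
    # Smallest voxel dose d with count(dose >= d) <= k; ties at a value can
    # push its count above k, in which case the next distinct value is the
    # answer.  If even the maximum's tied block exceeds k voxels (volume
    # below one voxel, or a uniform field), report the maximum.
    uniq = np.unique(asc)
    counts = n - np.searchsorted(asc, uniq, side="left")
    ok = uniq[counts <= k]
    return float(ok[0]) if ok.size else float(uniq[-1])


def cumulative_dvh(
    dose: DoseGrid,
    organ_mask: BinaryMask,
    bin_width_gy: float = 0.1,
    restrict_mask: BinaryMask | None = None,
) -> DVHCurve:
    """Cumulative DVH curve with left edges 0, w, 2w, ... covering the organ
    dose range; the value at each edge is the volume receiving >= that edge."""
    if bin_width_gy <= 0:
        raise ValueError("bin_width_gy must be > 0")
    doses = organ_doses(dose, organ_mask, restrict_mask)
    vox_cc = organ_mask.grid.voxel_volume_cc
    top = float(doses.max()) if doses.size else 0.0
    n_edges = int(np.ceil(top / bin_width_gy)) + 2
    edges = np.arange(n_edges) * bin_width_gy
    if doses.size == 0:
        return DVHCurve(edges, np.zeros_like(edges))
    asc = np.sort(doses)
    counts = asc.size - np.searchsorted(asc, edges, side="left")
    return DVHCurve(edges, counts * vox_cc)


def coverage(
    dose: DoseGrid,
    target_mask: BinaryMask,
    prescription_gy: float,
) -> float:
    """Percent of the target volume receiving at least the prescription."""
    if prescription_gy <= 0:
        raise ValueError("prescription_gy must be > 0")
    doses = organ_doses(dose, target_mask)
    if doses.size == 0:
        raise ValueError("coverage of an empty target is undefined")
    return 100.0 * float((doses >= prescription_gy).sum()) / doses.size
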