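"""Surrogate isotoxic dose painter.

The clinical step-and-shoot IMRT optimiser with Monte-Carlo dose is
replaced by a deterministic distance-based painter plus a per-organ dose
clamp.  The analysis downstream needs realistic *constraint geometry* —
steep dose gradients abutting the gastrointestinal organs at risk — not
deliverable beams, so the dose model is:

    dose(p) = max(background, prescription - gradient * dist(p, T_opt))

where ``T_opt`` is the target cropped a fixed margin away from the organs
at risk.  Adaptation re-derives ``T_opt`` on the day's anatomy and then
clamps each organ's dose so its V33Gy sits at (never above) the 1 cc
constraint, keeping the hottest allowed sub-volume untouched — which makes
adapted plans sit at the constraint boundary, as clinically re-optimised
isotoxic plans do.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import dvh
from .core import BinaryMask, DoseGrid, ImageGrid3D, PlanningError, StructureSet
from .geometry import crop_target, rasterize_structure

__all__ = [
    "PlanParams",
    "AdaptationDecision",
    "paint_scheduled_dose",
    "adapt_dose",
    "trigger_adaptation",
    "rasterize_anatomy",
]


@dataclass(frozen=True)
class PlanParams:
    """Knobs of the surrogate planner.

    ``falloff_gradient_gy_per_mm`` controls how punishing organ motion is:
    4 Gy/mm is steep (typical SBRT gradients are 1–5).  ``clamp_epsilon_gy``
    keeps clamped voxels clear of the inclusive >= threshold;
    ``transition_band_mm`` feathers the clamp into the surrounding dose.
    """

    prescription_gy: float = 50.0
    n_fractions: int = 5
    constraint_dose_gy: float = 33.0
    constraint_volume_cc: float = 1.0
    crop_margin_mm: float = 3.0
    falloff_gradient_gy_per_mm: float = 4.0
    background_dose_gy: float = 0.0
    coverage_gain_trigger_pct: float = 10.0
    clamp_epsilon_gy: float = 0.1
    transition_band_mm: float = 2.0
    supersampling: int = 2

    def __post_init__(self) -> None:
        if not (self.prescription_gy > self.constraint_dose_gy > self.background_dose_gy >= 0):
            raise ValueError("need prescription > constraint dose > background >= 0")
        if self.falloff_gradient_gy_per_mm <= 0:
            raise ValueError("falloff gradient must be > 0")
        if self.constraint_volume_cc <= 0:
            raise ValueError("constraint volume must be > 0")


@dataclass
class AdaptationDecision:
    """Outcome of the adapt-or-not check for one fraction."""

    adapt: bool
    constraint_violated: bool
    coverage_gain_feasible: bool
    organ_v_cc: dict[str, float] = field(default_factory=dict)
    scheduled_coverage_pct: float = float("nan")
    repainted_coverage_pct: float = float("nan")


def rasterize_anatomy(
    anatomy: StructureSet,
    grid: ImageGrid3D,
    supersampling: int = 2,
) -> dict[str, BinaryMask]:
    """Rasterise every structure of an anatomy onto one grid."""
    return {
        s.name: rasterize_structure(s, grid, supersampling=supersampling)
        for s in anatomy
    }


def _optimization_target(
    anatomy: StructureSet,
    grid: ImageGrid3D,
    params: PlanParams,
    masks: dict[str, BinaryMask] | None = None,
) -> tuple[BinaryMask, dict[str, BinaryMask]]:
    if masks is None:
        masks = rasterize_anatomy(anatomy, grid, params.supersampling)
    target = masks[anatomy.target.name]
    oars = [masks[s.name] for s in anatomy.gi_oars]
    opt = crop_target(target, oars, params.crop_margin_mm)
    return opt, masks


def _paint(opt: BinaryMask, params: PlanParams) -> np.ndarray:
    if not opt.occupancy.any():
        raise PlanningError(
            "optimisation target is empty after cropping; cannot paint dose"
        )
    dist = ndimage.distance_transform_edt(
        ~opt.occupancy, sampling=opt.grid.spacing
    )
    dose = params.prescription_gy - params.falloff_gradient_gy_per_mm * dist
    return np.maximum(dose, params.background_dose_gy)


def paint_scheduled_dose(
    anatomy: StructureSet,
    plan_params: PlanParams,
    grid: ImageGrid3D,
    masks: dict[str, BinaryMask] | None = None,
) -> DoseGrid:
    """Paint the isotoxic surrogate dose for one anatomy.

    Prescription dose inside the cropped optimisation target, linear
    fall-off with Euclidean distance outside, floored at the background
    level.  Deterministic.
    """
    if not anatomy.gi_oars:
        raise PlanningError("anatomy has no gastrointestinal organ at risk")
    opt, _ = _optimization_target(anatomy, grid, plan_params, masks)
    return DoseGrid(grid, _paint(opt, plan_params))


def _clamp_organ(
    dose: np.ndarray,
    organ: BinaryMask,
    allowed_cc: float,
    params: PlanParams,
    protect: np.ndarray,
) -> np.ndarray:
    """Clamp one organ's above-threshold voxels so its V33Gy <= allowed_cc.

    The hottest sub-volume of ``allowed_cc`` is kept untouched; the rest is
    set to (constraint dose - epsilon).  A feathering cap is applied in a
    band around the clamped pocket, excluding ``protect`` voxels (target
    and all organs).
    """
    grid = organ.grid
    vox_cc = grid.voxel_volume_cc
    thr = params.constraint_dose_gy
    organ_doses = dose[organ.occupancy]
    above = organ_doses >= thr
    v_cc = above.sum() * vox_cc
    if v_cc <= allowed_cc + 1e-12:
        return dose
    k_keep = int(np.floor(allowed_cc / vox_cc + 1e-12))
    idx = np.argwhere(organ.occupancy)
    above_idx = idx[above]
    above_doses = organ_doses[above]
    order = np.argsort(above_doses)[::-1]  # hottest first
    clamp_idx = above_idx[order[k_keep:]]
    out = dose.copy()
    clamp_value = thr - params.clamp_epsilon_gy
    out[tuple(clamp_idx.T)] = np.minimum(
        out[tuple(clamp_idx.T)], clamp_value
    )
    if params.transition_band_mm > 0:
        pocket = np.zeros(grid.shape, dtype=bool)
        pocket[tuple(clamp_idx.T)] = True
        dist = ndimage.distance_transform_edt(~pocket, sampling=grid.spacing)
        band = (dist <= params.transition_band_mm) & ~pocket & ~protect
        cap = clamp_value + params.falloff_gradient_gy_per_mm * dist[band]
        out[band] = np.minimum(out[band], cap)
    return out


def adapt_dose(
    scheduled_dose: DoseGrid,
    pre_anatomy: StructureSet,
    plan_params: PlanParams,
    masks: dict[str, BinaryMask] | None = None,
) -> tuple[DoseGrid, dict[str, object]]:
    """Re-optimise (surrogate) on the day's pre-treatment anatomy.

    Steps: (a) re-paint with the optimisation target recomputed on
    ``pre_anatomy``; (b) for each GI-OAR, clamp its above-threshold voxels
    down to ``min(constraint volume, scheduled V33Gy)`` — the re-optimiser
    prioritises organ sparing, so an adapted plan neither violates the
    constraint nor does worse than the scheduled plan at any organ.

    Returns the adapted dose and metadata recording which organs were
    clamped and any organ that overlapped the prescription region
    (resolved in favour of the organ).
    """
    grid = scheduled_dose.grid
    opt, masks = _optimization_target(pre_anatomy, grid, plan_params, masks)
    if not opt.occupancy.any():
        raise PlanningError(
            "optimisation target empty on pre-treatment anatomy; cannot adapt"
        )
    painted = _paint(opt, plan_params)

    target_name = pre_anatomy.target.name
    protect = masks[target_name].occupancy.copy()
    for s in pre_anatomy.gi_oars:
        protect |= masks[s.name].occupancy

    meta: dict[str, object] = {"clamped_organs": [], "oar_priority_conflicts": []}
    dose = painted
    for s in pre_anatomy.gi_oars:
        organ = masks[s.name]
        sched_v = dvh.v_at_dose(
            scheduled_dose, organ, plan_params.constraint_dose_gy
        )
        allowed = min(plan_params.constraint_volume_cc, sched_v)
        adapted_grid = DoseGrid(grid, dose)
        v_now = dvh.v_at_dose(adapted_grid, organ, plan_params.constraint_dose_gy)
        if v_now > allowed + 1e-12:
            if bool((organ.occupancy & opt.occupancy).any()):
                meta["oar_priority_conflicts"].append(s.name)
            dose = _clamp_organ(dose, organ, allowed, plan_params, protect)
            meta["clamped_organs"].append(s.name)
    return DoseGrid(grid, dose), meta


def trigger_adaptation(
    scheduled_dose: DoseGrid,
    pre_anatomy: StructureSet,
    plan_params: PlanParams,
    masks: dict[str, BinaryMask] | None = None,
) -> AdaptationDecision:
    """Decide whether the scheduled plan needs adaptation on today's anatomy.

    Adaptation is prompted when any GI-OAR's V33Gy on the pre-treatment
    anatomy exceeds the 1 cc constraint (the boundary value is compliant),
    or when re-painting on today's anatomy would gain at least 10
    percentage points of target coverage.
    """
    grid = scheduled_dose.grid
    if masks is None:
        masks = rasterize_anatomy(pre_anatomy, grid, plan_params.supersampling)
    organ_v = {
        s.name: dvh.v_at_dose(
            scheduled_dose, masks[s.name], plan_params.constraint_dose_gy
        )
        for s in pre_anatomy.gi_oars
    }
    violated = any(
        v > plan_params.constraint_volume_cc + 1e-12 for v in organ_v.values()
    )

    target = masks[pre_anatomy.target.name]
    sched_cov = dvh.coverage(scheduled_dose, target, plan_params.prescription_gy)
    try:
        repainted = paint_scheduled_dose(pre_anatomy, plan_params, grid, masks)
        repaint_cov = dvh.coverage(repainted, target, plan_params.prescription_gy)
    except PlanningError:
        repaint_cov = float("nan")
    gain = (
        not np.isnan(repaint_cov)
        and repaint_cov - sched_cov >= plan_params.coverage_gain_trigger_pct
    )
    return AdaptationDecision(
        adapt=bool(violated or gain),
        constraint_violated=bool(violated),
        coverage_gain_feasible=bool(gain),
        organ_v_cc=organ_v,
        scheduled_coverage_pct=sched_cov,
        repainted_coverage_pct=repaint_cov,
    )


def plan_on_anatomy(
    anatomy: StructureSet,
    plan_params: PlanParams,
    grid: ImageGrid3D,
    masks: dict[str, BinaryMask] | None = None,
) -> DoseGrid:
    """Paint + constraint-clamp on one anatomy: the plan a clinician would
    call isotoxic, meeting V33Gy <= 1 cc on its own planning anatomy.

    Used to build the scheduled (simulation) plan of a synthetic course.
    """
    opt, masks = _optimization_target(anatomy, grid, plan_params, masks)
    if not opt.occupancy.any():
        raise PlanningError("optimisation target is empty; cannot plan")
    painted = _paint(opt, plan_params)
    target_name = anatomy.target.name
    protect = masks[target_name].occupancy.copy()
    for s in anatomy.gi_oars:
        protect |= masks[s.name].occupancy
    dose = painted
    for s in anatomy.gi_oars:
        dose = _clamp_organ(
            dose,
            masks[s.name],
            plan_params.constraint_volume_cc,
            plan_params,
            protect,
        )
    return DoseGrid(grid, dose)
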