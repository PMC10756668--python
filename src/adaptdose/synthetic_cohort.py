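"""Synthetic abdominal cohorts with stochastic gastrointestinal motion.

The clinical MRIs behind the analysis are not public, so this module
generates anatomies with the same statistical structure the analysis
assumes: a pancreatic target (CTV) drawn as a randomised smooth blob with
volume in the clinical range (median 86 cc, range 36–145 cc), four
gastrointestinal organs at risk (duodenum, stomach, colon, small bowel)
modelled as curved tubes arranged around the target — the duodenum hugging
it, so at least one organ lies within 3 mm of the CTV — and a two-level
stochastic motion model:

* *inter*-fraction (day-to-day) variation perturbs the planning anatomy
  into each fraction's pre-treatment anatomy, large enough that most
  scheduled plans violate a constraint and require adaptation;
* *intra*-fraction peristalsis perturbs the pre-treatment anatomy into the
  post-treatment anatomy during the adaptive re-planning latency.

Both levels use the same displacement machinery: an organ-level rigid
translation drawn from an isotropic 3-D normal, plus a smooth band-limited
in-plane deformation field applied to contour vertices.  The target moves
only by a baseline-shift term, which registration later removes.

Seed policy: every random stream derives from one master seed via
``numpy`` ``SeedSequence(master_seed, spawn_key=(patient, fraction,
stream))`` so any single case is regenerable in isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from shapely.geometry import Polygon

from .core import (
    GI_ORGANS,
    TARGET_NAME,
    CaseBundle,
    GenerationError,
    ImageGrid3D,
    OrganClass,
    Structure,
    StructureSet,
)
from .geometry import min_surface_distance_mm, rasterize_structure
from .planner import PlanParams, adapt_dose, plan_on_anatomy, rasterize_anatomy

log = logging.getLogger(__name__)

__all__ = [
    "OrganShapeParams",
    "AnatomyParams",
    "MotionModelParams",
    "CohortParams",
    "generate_anatomy",
    "apply_peristalsis",
    "generate_cohort",
    "make_grid",
    "case_seed",
]


@dataclass(frozen=True)
class OrganShapeParams:
    """Curved-tube geometry of one organ at risk.

    ``gap_range_mm`` is the in-plane surface gap between the tube and the
    CTV at the organ's azimuth; ``radius_range_mm`` the tube radius.
    """

    gap_range_mm: tuple[float, float]
    radius_range_mm: tuple[float, float]
    z_extent_factor: tuple[float, float] = (0.8, 1.3)


#: Organ layout: the duodenum hugs the target (gap <= 2 mm guarantees the
#: within-3-mm criterion); the stomach sits close, the small bowel at
#: moderate distance, the colon furthest out.
DEFAULT_ORGAN_SHAPES: dict[str, OrganShapeParams] = {
    "duodenum": OrganShapeParams((0.5, 2.0), (8.0, 11.0)),
    "stomach": OrganShapeParams((3.0, 9.0), (15.0, 20.0)),
    "small_bowel": OrganShapeParams((6.0, 14.0), (9.0, 13.0)),
    "colon": OrganShapeParams((14.0, 24.0), (10.0, 14.0)),
}


def _default_grid() -> ImageGrid3D:
    # 1.6 mm in-plane, 3 mm slices (clinical MRI voxel); 20 x 20 x 14.4 cm FOV
    shape = (125, 125, 48)
    spacing = (1.6, 1.6, 3.0)
    origin = tuple(-(n - 1) * s / 2.0 for n, s in zip(shape, spacing))
    return ImageGrid3D(origin, spacing, shape)


def make_grid(spacing_mm: tuple[float, float, float], fov_mm=(200.0, 200.0, 144.0)) -> ImageGrid3D:
    """Axis-aligned grid centred on the origin with a given spacing/FOV."""
    shape = tuple(max(1, int(round(f / s))) for f, s in zip(fov_mm, spacing_mm))
    origin = tuple(-(n - 1) * s / 2.0 for n, s in zip(shape, spacing_mm))
    return ImageGrid3D(origin, spacing_mm, shape)


@dataclass(frozen=True)
class AnatomyParams:
    """Cohort geometry parameters.

    CTV volumes are drawn from a log-normal with the clinical median,
    truncated to the clinical range; organ tubes follow
    :data:`DEFAULT_ORGAN_SHAPES`.
    """

    ctv_volume_range_cc: tuple[float, float] = (36.0, 145.0)
    ctv_volume_median_cc: float = 86.0
    ctv_volume_log_sd: float = 0.38
    organ_shapes: dict[str, OrganShapeParams] = field(
        default_factory=lambda: dict(DEFAULT_ORGAN_SHAPES)
    )
    min_organ_target_gap_mm: float = 3.0
    n_polygon_vertices: int = 40
    grid: ImageGrid3D = field(default_factory=_default_grid)
    max_retries: int = 8

    def with_grid(self, grid: ImageGrid3D) -> "AnatomyParams":
        return replace(self, grid=grid)


@dataclass(frozen=True)
class MotionModelParams:
    """One level of the stochastic displacement model (all mm)."""

    translation_mean_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation_sigma_mm: float = 3.0
    deformation_amplitude_mm: float = 2.0
    deformation_correlation_mm: float = 30.0
    target_shift_sigma_mm: float = 2.0

    def __post_init__(self) -> None:
        if self.translation_sigma_mm < 0 or self.deformation_amplitude_mm < 0:
            raise ValueError("sigma and amplitude must be >= 0")
        if self.target_shift_sigma_mm < 0:
            raise ValueError("target shift sigma must be >= 0")
        if self.deformation_correlation_mm <= 0:
            raise ValueError("correlation length must be > 0")


#: Day-to-day anatomical variation: larger than the intrafraction level so
#: that (as clinically observed) the majority of scheduled plans violate a
#: constraint on the day's anatomy.  The target term is zero because couch
#: registration has already aligned the target at localisation.
DEFAULT_INTERFRACTION = MotionModelParams(
    translation_sigma_mm=5.0,
    deformation_amplitude_mm=3.0,
    deformation_correlation_mm=40.0,
    target_shift_sigma_mm=0.0,
)

#: Peristalsis during the adaptive-planning latency (moderate motion).
DEFAULT_INTRAFRACTION = MotionModelParams(
    translation_sigma_mm=3.0,
    deformation_amplitude_mm=2.0,
    deformation_correlation_mm=30.0,
    target_shift_sigma_mm=2.0,
)


# ---------------------------------------------------------------------------
# Anatomy generation


class _CtvShape:
    """Randomised smooth blob: ellipsoid with low-order angular perturbation."""

    def __init__(self, rng: np.random.Generator, params: AnatomyParams):
        lo, hi = params.ctv_volume_range_cc
        for _ in range(100):
            v = params.ctv_volume_median_cc * float(
                np.exp(params.ctv_volume_log_sd * rng.standard_normal())
            )
            if lo <= v <= hi:
                break
        else:
            v = params.ctv_volume_median_cc
        self.volume_cc = v
        abc = 3.0 * (v * 1000.0) / (4.0 * np.pi)  # a*b*c in mm^3
        self.ratio = float(rng.uniform(0.8, 1.25))
        rc = float(rng.uniform(0.75, 1.05))
        s = (abc / rc) ** (1.0 / 3.0)
        self.a = s * self.ratio
        self.b = s / self.ratio
        self.c = s * rc
        # low-order Fourier perturbation of the in-plane radius
        self.modes = [
            (m, float(rng.uniform(0.0, 0.08)), float(rng.uniform(0, 2 * np.pi)))
            for m in (2, 3)
        ]
        self.scale = 1.0

    def inplane_radius(self, phi: np.ndarray, z: float) -> np.ndarray:
        zc = np.clip(z / self.c, -0.999, 0.999)
        shrink = np.sqrt(1.0 - zc**2)
        base = self.a * self.b / np.sqrt(
            (self.b * np.cos(phi)) ** 2 + (self.a * np.sin(phi)) ** 2
        )
        pert = np.ones_like(phi)
        for m, eps, psi in self.modes:
            pert += eps * np.cos(m * phi + psi)
        return self.scale * shrink * base * pert

    def slice_polygon(self, z: float, n_vertices: int) -> np.ndarray:
        phi = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
        r = self.inplane_radius(phi, z)
        return np.column_stack([r * np.cos(phi), r * np.sin(phi)])


def _smooth_profile(
    rng: np.random.Generator, zs: np.ndarray, lo: float, hi: float
) -> np.ndarray:
    """Smooth random profile over the slice stack, valued in [lo, hi]."""
    mid = rng.uniform(lo, hi)
    amp = (hi - lo) / 2.0
    ph = rng.uniform(0, 2 * np.pi)
    span = max(zs[-1] - zs[0], 1.0)
    prof = mid + amp * 0.5 * np.sin(2 * np.pi * zs / span + ph)
    return np.clip(prof, lo, hi)


def _build_ctv(
    rng: np.random.Generator, params: AnatomyParams
) -> tuple[Structure, _CtvShape]:
    shape = _CtvShape(rng, params)
    grid = params.grid
    dz = grid.spacing[2]
    zs = grid.axis_coords(2)
    covered = zs[np.abs(zs) < shape.c - 0.25 * dz]
    if covered.size < 3:
        raise GenerationError("CTV spans fewer than 3 slices on this grid")
    contours = [
        (float(z), [shape.slice_polygon(float(z), params.n_polygon_vertices)])
        for z in covered
    ]
    ctv = Structure(TARGET_NAME, OrganClass.TARGET, contours)
    # one analytic rescale so the contour-stack volume hits the sampled value
    stack_cc = sum(Polygon(p[0]).area for _, p in ctv.contours) * dz / 1000.0
    shape.scale = float(np.sqrt(shape.volume_cc / stack_cc))
    contours = [
        (float(z), [shape.slice_polygon(float(z), params.n_polygon_vertices)])
        for z in covered
    ]
    return Structure(TARGET_NAME, OrganClass.TARGET, contours), shape


def _build_organ(
    rng: np.random.Generator,
    name: str,
    shape_params: OrganShapeParams,
    ctv: _CtvShape,
    azimuth: float,
    params: AnatomyParams,
) -> Structure:
    grid = params.grid
    dz = grid.spacing[2]
    zs = grid.axis_coords(2)
    zf_lo, zf_hi = shape_params.z_extent_factor
    half_extent = ctv.c * rng.uniform(zf_lo, zf_hi)
    z_center = rng.uniform(-0.2, 0.2) * ctv.c
    covered = zs[np.abs(zs - z_center) < half_extent]
    if covered.size < 2:
        covered = zs[np.argsort(np.abs(zs - z_center))[:2]]
        covered = np.sort(covered)

    gaps = _smooth_profile(rng, covered, *shape_params.gap_range_mm)
    radii = _smooth_profile(rng, covered, *shape_params.radius_range_mm)
    wobble_amp = np.deg2rad(rng.uniform(2.0, 10.0))
    wobble_ph = rng.uniform(0, 2 * np.pi)
    span = max(covered[-1] - covered[0], 1.0)

    fov_half = min(
        -grid.origin[0], -grid.origin[1],
        grid.origin[0] + grid.spacing[0] * (grid.shape[0] - 1),
        grid.origin[1] + grid.spacing[1] * (grid.shape[1] - 1),
    )
    n = params.n_polygon_vertices
    phi_pts = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    contours = []
    for z, gap, r_t in zip(covered, gaps, radii):
        phi_c = azimuth + wobble_amp * np.sin(2 * np.pi * (z - covered[0]) / span + wobble_ph)
        r_ctv = float(ctv.inplane_radius(np.asarray([phi_c]), float(z))[0])
        rho = r_ctv + gap + r_t
        rho = min(rho, fov_half - r_t - 3.0)  # stay inside the field of view
        cx, cy = rho * np.cos(phi_c), rho * np.sin(phi_c)
        ell = rng.uniform(0.9, 1.1)
        poly = np.column_stack(
            [cx + r_t * ell * np.cos(phi_pts), cy + (r_t / ell) * np.sin(phi_pts)]
        )
        contours.append((float(z), [poly]))
    return Structure(name, OrganClass.GI_OAR, contours)


def generate_anatomy(
    params: AnatomyParams | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[StructureSet, ImageGrid3D]:
    """Generate one synthetic planning anatomy.

    Returns a structure set (CTV + the four GI-OARs, in fixed order) and
    the grid it was designed on.  Deterministic for a fixed seed.
    Raises :class:`GenerationError` if the geometric constraints cannot be
    met after bounded retries.
    """
    params = params or AnatomyParams()
    rng = np.random.default_rng(seed)
    lo, hi = params.ctv_volume_range_cc
    last_err = "unknown"
    for _ in range(params.max_retries):
        try:
            ctv_struct, ctv_shape = _build_ctv(rng, params)
        except GenerationError as exc:
            last_err = str(exc)
            continue
        base_angles = np.deg2rad(np.asarray([0.0, 90.0, 180.0, 270.0]))
        base_angles = base_angles + rng.uniform(0, 2 * np.pi)
        base_angles = rng.permutation(base_angles)
        organs = [
            _build_organ(
                rng, name, params.organ_shapes[name], ctv_shape,
                float(base_angles[i] + rng.uniform(-0.3, 0.3)), params,
            )
            for i, name in enumerate(GI_ORGANS)
        ]
        anatomy = StructureSet([ctv_struct] + organs)

        ctv_mask = rasterize_structure(ctv_struct, params.grid)
        vol = ctv_mask.volume_cc
        if not (lo <= vol <= hi):
            last_err = f"rasterised CTV volume {vol:.1f} cc outside [{lo}, {hi}]"
            continue
        duo_mask = rasterize_structure(anatomy["duodenum"], params.grid)
        gap = min_surface_distance_mm(duo_mask, ctv_mask)
        if gap > params.min_organ_target_gap_mm:
            last_err = f"closest organ sits {gap:.1f} mm from the CTV (> 3 mm)"
            continue
        return anatomy, params.grid
    raise GenerationError(f"anatomy generation failed: {last_err}")


# ---------------------------------------------------------------------------
# Motion


def _deformation_field(
    rng: np.random.Generator,
    vertices: np.ndarray,
    amplitude: float,
    correlation: float,
) -> np.ndarray:
    """Smooth in-plane random displacement at (N, 3) vertex positions.

    Band-limited noise: i.i.d. normal node values on a lattice with node
    spacing equal to the correlation length, interpolated to the vertices.
    """
    if amplitude == 0 or len(vertices) == 0:
        return np.zeros((len(vertices), 2))
    lo = vertices.min(axis=0) - correlation
    hi = vertices.max(axis=0) + correlation
    axes = [
        np.arange(lo[d], hi[d] + correlation, correlation) for d in range(3)
    ]
    axes = [ax if len(ax) >= 2 else np.asarray([lo[d], lo[d] + correlation]) for d, ax in enumerate(axes)]
    nodes = rng.normal(0.0, amplitude, size=tuple(len(a) for a in axes) + (2,))
    interp = RegularGridInterpolator(
        axes, nodes, method="linear", bounds_error=False, fill_value=0.0
    )
    return interp(vertices)


def _displace_structure(
    s: Structure,
    translation: np.ndarray,
    rng: np.random.Generator,
    amplitude: float,
    correlation: float,
) -> Structure:
    verts = s.all_vertices()
    for attempt in range(5):
        deform = _deformation_field(rng, verts, amplitude, correlation)
        out_contours = []
        i = 0
        ok = True
        for z, polys in s.contours:
            new_polys = []
            for p in polys:
                d = deform[i : i + len(p)]
                q = p + translation[:2] + d
                if not Polygon(q).is_valid:
                    ok = False
                new_polys.append(q)
                i += len(p)
            out_contours.append((z + translation[2], new_polys))
        if ok:
            return Structure(s.name, s.organ_class, out_contours)
        amplitude *= 0.5
        log.warning(
            "structure %r: deformation produced a self-intersecting polygon; "
            "amplitude backed off to %.2f mm", s.name, amplitude,
        )
    # translation alone can never invalidate a polygon
    return s.translated(translation)


def apply_peristalsis(
    anatomy: StructureSet,
    motion_params: MotionModelParams,
    seed: int | np.random.SeedSequence = 0,
) -> StructureSet:
    """Displace an anatomy by one draw of the stochastic motion model.

    Each GI-OAR receives an organ-level rigid translation plus a smooth
    in-plane deformation; the target receives only a baseline-shift
    translation (removed later by registration); other structures are
    untouched.  Deterministic for a fixed seed.  With all magnitudes zero
    the anatomy is returned unchanged.
    """
    rng = np.random.default_rng(seed)
    out = []
    for s in anatomy:
        if s.organ_class is OrganClass.GI_OAR:
            t = np.asarray(motion_params.translation_mean_mm) + (
                motion_params.translation_sigma_mm * rng.standard_normal(3)
            )
            if motion_params.deformation_amplitude_mm == 0:
                out.append(s.translated(t) if np.any(t != 0) else s)
            else:
                out.append(
                    _displace_structure(
                        s, t, rng,
                        motion_params.deformation_amplitude_mm,
                        motion_params.deformation_correlation_mm,
                    )
                )
        elif s.organ_class is OrganClass.TARGET:
            shift = motion_params.target_shift_sigma_mm * rng.standard_normal(3)
            out.append(s.translated(shift) if np.any(shift != 0) else s)
        else:
            out.append(s)
    return StructureSet(out)


# ---------------------------------------------------------------------------
# Cohort


@dataclass(frozen=True)
class CohortParams:
    """Study conditions of a simulated course: 10 patients x 5 fractions
    of 50 Gy, with day-to-day and within-fraction motion."""

    n_patients: int = 10
    n_fractions: int = 5
    anatomy: AnatomyParams = field(default_factory=AnatomyParams)
    interfraction: MotionModelParams = DEFAULT_INTERFRACTION
    intrafraction: MotionModelParams = DEFAULT_INTRAFRACTION
    plan: PlanParams = field(default_factory=PlanParams)

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.n_fractions < 1:
            raise ValueError("need at least one patient and one fraction")


# stream ids of the seed-derivation scheme
_STREAM_ANATOMY, _STREAM_INTERFRACTION, _STREAM_INTRAFRACTION = 0, 1, 2


def case_seed(master_seed: int, patient: int, fraction: int, stream: int) -> np.random.SeedSequence:
    """SeedSequence for one (patient, fraction, stream) cell.

    ``fraction`` is 0 for per-patient streams (anatomy); streams are
    0 = anatomy, 1 = inter-fraction motion, 2 = intra-fraction motion.
    """
    return np.random.SeedSequence(master_seed, spawn_key=(patient, fraction, stream))


def generate_cohort(
    params: CohortParams | None = None,
    master_seed: int = 0,
    progress: bool = False,
) -> list[CaseBundle]:
    """Simulate a full course: per patient one base anatomy and scheduled
    plan, per fraction a pre-treatment anatomy, an adapted plan and a
    post-treatment anatomy.

    Returns ``n_patients * n_fractions`` case bundles, deterministic for a
    fixed master seed.
    """
    params = params or CohortParams()
    grid = params.anatomy.grid
    bundles: list[CaseBundle] = []
    for p in range(params.n_patients):
        patient_id = f"P{p + 1:02d}"
        anatomy, _ = generate_anatomy(
            params.anatomy, seed=case_seed(master_seed, p, 0, _STREAM_ANATOMY)
        )
        scheduled = plan_on_anatomy(anatomy, params.plan, grid)
        for f in range(1, params.n_fractions + 1):
            pre = apply_peristalsis(
                anatomy, params.interfraction,
                seed=case_seed(master_seed, p, f, _STREAM_INTERFRACTION),
            )
            pre_masks = rasterize_anatomy(pre, grid, params.plan.supersampling)
            adapted, plan_meta = adapt_dose(scheduled, pre, params.plan, pre_masks)
            post = apply_peristalsis(
                pre, params.intrafraction,
                seed=case_seed(master_seed, p, f, _STREAM_INTRAFRACTION),
            )
            bundles.append(
                CaseBundle(
                    patient_id=patient_id,
                    fraction_index=f,
                    pre_anatomy=pre,
                    post_anatomy=post,
                    scheduled_dose=scheduled,
                    adapted_dose=adapted,
                    metadata={
                        "master_seed": int(master_seed),
                        "patient_index": p,
                        "clamped_organs": list(plan_meta["clamped_organs"]),
                        "oar_priority_conflicts": list(
                            plan_meta["oar_priority_conflicts"]
                        ),
                    },
                )
            )
            if progress:
                log.info("simulated %s fraction %d", patient_id, f)
    return bundles
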