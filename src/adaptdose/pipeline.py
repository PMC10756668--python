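"""The analysis proper: target-focused rigid registration, three-time-point
evaluation of every fraction, and cohort summaries.

Each fraction yields one V33Gy record per GI-OAR at three time points:

1. ``scheduled_pre`` — the scheduled plan on the pre-treatment anatomy
   (what would have been delivered without adaptation);
2. ``adapted_pre``  — the adapted plan on the pre-treatment anatomy
   (what the re-optimiser achieved; <= 1 cc by construction);
3. ``adapted_post`` — the adapted plan on the post-treatment anatomy
   (what was effectively delivered after intrafraction motion).

Post-treatment anatomy is first rigidly registered to the pre-treatment
anatomy by aligning the target centroids (translation only), so residual
organ change is attributed to peristalsis alone.

Conventions, recorded in every report: the constraint is compliance with
V33Gy <= 1 cc, so *exceedance* is strict (> 1 cc); better/worse
comparisons are strict inequalities with exact ties counted separately;
reported percentages are rounded half-away-from-zero to integers, with the
exact fractions retained.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dvh
from .core import BinaryMask, CaseBundle, ImageGrid3D, StructureSet
from .geometry import mask_centroid_mm, rasterize_structure, ring_region
from .planner import PlanParams, rasterize_anatomy

log = logging.getLogger(__name__)

__all__ = [
    "Timepoint",
    "MetricRecord",
    "CohortSummary",
    "register_rigid",
    "evaluate_fraction",
    "evaluate_cohort",
    "summarize_cohort",
    "render_report",
    "round_half_away",
]

DEFAULT_CUTOFFS_CC = (0.035, 0.5, 1.0, 2.0, 3.0, 4.0, 5.0)


class Timepoint(str, enum.Enum):
    SCHEDULED_PRE = "scheduled_pre"
    ADAPTED_PRE = "adapted_pre"
    ADAPTED_POST = "adapted_post"


@dataclass(frozen=True)
class MetricRecord:
    """V33Gy (and auxiliaries) for one (patient, fraction, organ, timepoint)."""

    patient_id: str
    fraction_index: int
    organ: str
    timepoint: Timepoint
    v33_cc: float
    coverage_pct: float = float("nan")
    aux: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.v33_cc < 0:
            raise ValueError("v33_cc must be >= 0")


def records_to_frame(records: list[MetricRecord]) -> pd.DataFrame:
    rows = [
        {
            "patient_id": r.patient_id,
            "fraction_index": r.fraction_index,
            "organ": r.organ,
            "timepoint": r.timepoint.value,
            "v33_cc": r.v33_cc,
            "coverage_pct": r.coverage_pct,
            **{f"aux_{k}": v for k, v in r.aux.items()},
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def round_half_away(x: float) -> int:
    """Round half away from zero (23/35 -> 66%), unlike banker's rounding."""
    return int(np.floor(abs(x) + 0.5) * np.sign(x)) if np.isfinite(x) else x


# ---------------------------------------------------------------------------
# Registration


def register_rigid(
    post_anatomy: StructureSet,
    pre_anatomy: StructureSet,
    grid: ImageGrid3D,
    supersampling: int = 2,
) -> tuple[np.ndarray, StructureSet]:
    """Translation-only rigid registration focused on the target.

    Aligns the post-treatment target's rasterised centroid to the
    pre-treatment target's centroid and applies that translation to every
    post-treatment structure.  Rotation is fixed to identity, matching
    couch-translation-only localisation.
    """
    pre_target = pre_anatomy.target
    post_target = post_anatomy.target
    pre_c = mask_centroid_mm(rasterize_structure(pre_target, grid, supersampling))
    post_c = mask_centroid_mm(rasterize_structure(post_target, grid, supersampling))
    t = pre_c - post_c
    moved = StructureSet([s.translated(t) for s in post_anatomy])
    return t, moved


# ---------------------------------------------------------------------------
# Per-fraction evaluation


def evaluate_fraction(
    case: CaseBundle,
    plan_params: PlanParams | None = None,
    ring_mode: bool = True,
    ring_radius_mm: float = 30.0,
    strict_threshold: bool = False,
) -> list[MetricRecord]:
    """Three-time-point V33Gy evaluation of one fraction.

    With ``ring_mode`` on, organ masks are restricted to a
    ``ring_radius_mm`` shell around the (pre-treatment) target before
    metric evaluation.  Auxiliary D0.035cc is reported per record.
    """
    plan_params = plan_params or PlanParams()
    grid = case.grid
    ss = plan_params.supersampling
    pre_masks = rasterize_anatomy(case.pre_anatomy, grid, ss)
    _, post_reg = register_rigid(case.post_anatomy, case.pre_anatomy, grid, ss)
    post_masks = rasterize_anatomy(post_reg, grid, ss)

    target_name = case.pre_anatomy.target.name
    restrict = None
    if ring_mode:
        restrict = ring_region(pre_masks[target_name], ring_radius_mm)

    thr = plan_params.constraint_dose_gy
    records: list[MetricRecord] = []
    settings = [
        (Timepoint.SCHEDULED_PRE, case.scheduled_dose, pre_masks),
        (Timepoint.ADAPTED_PRE, case.adapted_dose, pre_masks),
        (Timepoint.ADAPTED_POST, case.adapted_dose, post_masks),
    ]
    for tp, dose_grid, masks in settings:
        cov = dvh.coverage(
            dose_grid, masks[target_name], plan_params.prescription_gy
        )
        for organ_struct in case.pre_anatomy.gi_oars:
            organ = organ_struct.name
            mask = masks[organ]
            v33 = dvh.v_at_dose(
                dose_grid, mask, thr, restrict_mask=restrict, strict=strict_threshold
            )
            aux = {}
            eval_occ = mask.occupancy
            if restrict is not None:
                eval_occ = eval_occ & restrict.occupancy
            eval_cc = float(eval_occ.sum()) * grid.voxel_volume_cc
            if eval_cc >= 0.035:
                aux["d0.035cc_gy"] = dvh.d_at_volume(
                    dose_grid, mask, 0.035, restrict_mask=restrict
                )
            records.append(
                MetricRecord(
                    patient_id=case.patient_id,
                    fraction_index=case.fraction_index,
                    organ=organ,
                    timepoint=tp,
                    v33_cc=v33,
                    coverage_pct=cov,
                    aux=aux,
                )
            )
    return records


def evaluate_cohort(
    cases: list[CaseBundle],
    plan_params: PlanParams | None = None,
    ring_mode: bool = True,
    ring_radius_mm: float = 30.0,
    strict_threshold: bool = False,
    progress: bool = False,
) -> list[MetricRecord]:
    """Evaluate every fraction of a cohort."""
    records: list[MetricRecord] = []
    for case in cases:
        records.extend(
            evaluate_fraction(
                case, plan_params, ring_mode, ring_radius_mm, strict_threshold
            )
        )
        if progress:
            log.info("evaluated %s fraction %d", case.patient_id, case.fraction_index)
    return records


# ---------------------------------------------------------------------------
# Cohort summary


@dataclass
class CohortSummary:
    """All cohort-level tabulations.

    ``exceedance``: per organ x timepoint, percent of fractions with
    V33Gy strictly above the constraint.
    ``v33_stats``: per organ x timepoint median and range of V33Gy.
    ``patient_means``: per patient x organ, mean V33Gy over fractions for
    the scheduled and post-treatment evaluations.
    ``patients_exceeding``: per organ, number of patients whose mean
    exceeds the constraint (scheduled and post-treatment).
    ``motion_impact``: per organ, percent of fractions where the
    post-treatment V33Gy strictly exceeds the adapted (pre) value, plus a
    tie column.
    ``benefit``: per organ, among fractions whose *scheduled* V33Gy
    exceeded the constraint, the percent whose post-treatment V33Gy is
    strictly smaller than scheduled (NaN when no fraction exceeded).
    ``sweep``: percent of all fractions with V33Gy >= cutoff for each
    organ x timepoint x cutoff.
    """

    exceedance: pd.DataFrame
    v33_stats: pd.DataFrame
    patient_means: pd.DataFrame
    patients_exceeding: pd.DataFrame
    motion_impact: pd.DataFrame
    benefit: pd.DataFrame
    sweep: pd.DataFrame
    n_fractions: int
    n_patients: int
    conventions: dict = field(default_factory=dict)


def _pivot(frame: pd.DataFrame) -> pd.DataFrame:
    return frame.pivot_table(
        index=["patient_id", "fraction_index", "organ"],
        columns="timepoint",
        values="v33_cc",
    ).reset_index()


def summarize_cohort(
    records: list[MetricRecord] | pd.DataFrame,
    plan_params: PlanParams | None = None,
    cutoffs_cc: tuple[float, ...] = DEFAULT_CUTOFFS_CC,
    conventions: dict | None = None,
) -> CohortSummary:
    """Compute every cohort tabulation from the per-fraction records."""
    plan_params = plan_params or PlanParams()
    limit = plan_params.constraint_volume_cc
    frame = (
        records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    )
    if frame.empty:
        raise ValueError("cannot summarise an empty record set")
    organs = list(dict.fromkeys(frame["organ"]))
    timepoints = [tp.value for tp in Timepoint if tp.value in set(frame["timepoint"])]

    # (a) exceedance percentages: strict > constraint (<= is compliant)
    rows = []
    for organ in organs:
        for tp in timepoints:
            sub = frame[(frame.organ == organ) & (frame.timepoint == tp)]
            pct = 100.0 * (sub.v33_cc > limit).mean()
            rows.append(
                {
                    "organ": organ,
                    "timepoint": tp,
                    "n_fractions": len(sub),
                    "pct_exceeding": pct,
                    "pct_exceeding_rounded": round_half_away(pct),
                }
            )
    exceedance = pd.DataFrame(rows)

    # (b) median and range of V33Gy per organ x timepoint
    rows = []
    for organ in organs:
        for tp in timepoints:
            v = frame[(frame.organ == organ) & (frame.timepoint == tp)].v33_cc
            rows.append(
                {
                    "organ": organ,
                    "timepoint": tp,
                    "median_cc": float(v.median()),
                    "min_cc": float(v.min()),
                    "max_cc": float(v.max()),
                }
            )
    v33_stats = pd.DataFrame(rows)

    # (c) per-patient means over fractions, and patients exceeding on average
    mean_tps = [
        tp for tp in (Timepoint.SCHEDULED_PRE.value, Timepoint.ADAPTED_POST.value)
        if tp in timepoints
    ]
    pm = (
        frame[frame.timepoint.isin(mean_tps)]
        .groupby(["patient_id", "organ", "timepoint"], sort=False)
        .agg(mean_v33_cc=("v33_cc", "mean"), n_fractions=("v33_cc", "size"))
        .reset_index()
    )
    expected_n = frame.groupby("patient_id")["fraction_index"].nunique().max()
    pm["partial_course"] = pm["n_fractions"] < expected_n
    rows = []
    for organ in organs:
        row = {"organ": organ}
        for tp in mean_tps:
            sub = pm[(pm.organ == organ) & (pm.timepoint == tp)]
            row[f"n_patients_exceeding_{tp}"] = int((sub.mean_v33_cc > limit).sum())
        rows.append(row)
    patients_exceeding = pd.DataFrame(rows)

    # (d)/(e) paired comparisons per fraction
    has_pair = {
        Timepoint.ADAPTED_PRE.value,
        Timepoint.ADAPTED_POST.value,
        Timepoint.SCHEDULED_PRE.value,
    } <= set(timepoints)
    motion_rows, benefit_rows = [], []
    if has_pair:
        wide = _pivot(frame)
        for organ in organs:
            sub = wide[wide.organ == organ]
            post, pre, sched = (
                sub[Timepoint.ADAPTED_POST.value],
                sub[Timepoint.ADAPTED_PRE.value],
                sub[Timepoint.SCHEDULED_PRE.value],
            )
            inc = 100.0 * (post > pre).mean()
            motion_rows.append(
                {
                    "organ": organ,
                    "n_fractions": len(sub),
                    "pct_post_gt_adapted": inc,
                    "pct_post_gt_adapted_rounded": round_half_away(inc),
                    "pct_ties": 100.0 * (post == pre).mean(),
                }
            )
            exceeded = sched > limit
            n_exc = int(exceeded.sum())
            if n_exc:
                n_better = int((post[exceeded] < sched[exceeded]).sum())
                pct = 100.0 * n_better / n_exc
            else:
                n_better, pct = 0, float("nan")
            benefit_rows.append(
                {
                    "organ": organ,
                    "n_scheduled_exceeding": n_exc,
                    "n_post_below_scheduled": n_better,
                    "pct_benefit": pct,
                    "pct_benefit_rounded": (
                        round_half_away(pct) if n_exc else None
                    ),
                }
            )
    motion_impact = pd.DataFrame(motion_rows)
    benefit = pd.DataFrame(benefit_rows)

    # (f) cutoff sweep: percent of fractions with V33Gy >= cutoff
    rows = []
    for organ in organs:
        for tp in timepoints:
            sub = frame[(frame.organ == organ) & (frame.timepoint == tp)]
            for c in cutoffs_cc:
                pct = 100.0 * (sub.v33_cc >= c).mean()
                rows.append(
                    {
                        "organ": organ,
                        "timepoint": tp,
                        "cutoff_cc": c,
                        "pct_at_least": pct,
                        "pct_at_least_rounded": round_half_away(pct),
                    }
                )
    sweep = pd.DataFrame(rows)

    return CohortSummary(
        exceedance=exceedance,
        v33_stats=v33_stats,
        patient_means=pm,
        patients_exceeding=patients_exceeding,
        motion_impact=motion_impact,
        benefit=benefit,
        sweep=sweep,
        n_fractions=int(
            frame.groupby(["patient_id", "fraction_index"]).ngroups
        ),
        n_patients=int(frame.patient_id.nunique()),
        conventions=dict(conventions or {}),
    )


# ---------------------------------------------------------------------------
# Reporting


def _style_table(summary: CohortSummary) -> pd.DataFrame:
    """Median (range) per organ/timepoint plus patients-exceeding columns."""
    stats = summary.v33_stats.pivot(index="organ", columns="timepoint")
    rows = []
    for organ in summary.v33_stats.organ.unique():
        row = {"organ": organ}
        for tp in summary.v33_stats.timepoint.unique():
            med = stats.loc[organ, ("median_cc", tp)]
            lo = stats.loc[organ, ("min_cc", tp)]
            hi = stats.loc[organ, ("max_cc", tp)]
            row[tp] = f"{med:.1f} ({lo:.1f}-{hi:.1f})"
        pe = summary.patients_exceeding
        for col in pe.columns:
            if col != "organ":
                row[col] = int(pe.loc[pe.organ == organ, col].iloc[0])
        rows.append(row)
    return pd.DataFrame(rows)


def render_report(
    summary: CohortSummary,
    out_dir: str | Path,
    records: list[MetricRecord] | pd.DataFrame | None = None,
    make_plots: bool = True,
) -> dict[str, Path]:
    """Write CSV tables, summary plots and a run manifest.

    Outputs: ``records.csv`` (if records given), ``exceedance.csv``,
    ``summary_table.csv`` (median/range layout), ``benefit.csv``,
    ``motion_impact.csv``, ``sweep.csv``, ``v33_by_timepoint.png`` (strip
    plot), ``sweep.png`` (cutoff curves), ``manifest.yaml``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def _csv(name: str, df: pd.DataFrame) -> None:
        p = out / f"{name}.csv"
        df.to_csv(p, index=False, float_format="%.6g")
        written[name] = p

    rec_frame = None
    if records is not None:
        rec_frame = (
            records if isinstance(records, pd.DataFrame) else records_to_frame(records)
        )
        _csv("records", rec_frame)
    _csv("exceedance", summary.exceedance)
    _csv("summary_table", _style_table(summary))
    _csv("v33_stats", summary.v33_stats)
    _csv("patient_means", summary.patient_means)
    _csv("benefit", summary.benefit)
    _csv("motion_impact", summary.motion_impact)
    _csv("sweep", summary.sweep)

    manifest = {
        "n_patients": summary.n_patients,
        "n_fractions": summary.n_fractions,
        "conventions": summary.conventions,
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    written["manifest"] = out / "manifest.yaml"

    if make_plots:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        if rec_frame is not None:
            organs = list(dict.fromkeys(rec_frame["organ"]))
            tps = [tp.value for tp in Timepoint]
            fig, axes = plt.subplots(1, 3, figsize=(12, 4), sharey=True)
            rng = np.random.default_rng(0)  # jitter only
            for ax, tp in zip(axes, tps):
                sub = rec_frame[rec_frame.timepoint == tp]
                for i, organ in enumerate(organs):
                    v = sub[sub.organ == organ].v33_cc
                    x = i + rng.uniform(-0.2, 0.2, len(v))
                    ax.plot(x, v, "o", ms=3, alpha=0.6)
                ax.axhline(1.0, color="k", ls="--", lw=0.8)
                ax.set_xticks(range(len(organs)))
                ax.set_xticklabels(organs, rotation=45, ha="right")
                ax.set_title(tp)
            axes[0].set_ylabel("V33Gy (cc)")
            fig.tight_layout()
            fig.savefig(out / "v33_by_timepoint.png", dpi=120)
            plt.close(fig)
            written["v33_by_timepoint"] = out / "v33_by_timepoint.png"

        organs = list(dict.fromkeys(summary.sweep["organ"]))
        fig, axes = plt.subplots(
            1, len(organs), figsize=(3.2 * len(organs), 3.4), sharey=True
        )
        axes = np.atleast_1d(axes)
        for ax, organ in zip(axes, organs):
            sub = summary.sweep[summary.sweep.organ == organ]
            for tp, marker in zip(
                [t.value for t in Timepoint], ("s-", "^-", "o-")
            ):
                s = sub[sub.timepoint == tp]
                if len(s):
                    ax.plot(s.cutoff_cc, s.pct_at_least, marker, label=tp, ms=4)
            ax.set_title(organ)
            ax.set_xlabel("V33Gy cutoff (cc)")
        axes[0].set_ylabel("% of fractions at or above cutoff")
        axes[-1].legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out / "sweep.png", dpi=120)
        plt.close(fig)
        written["sweep"] = out / "sweep.png"
    return written
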