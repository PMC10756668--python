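# Methods

This note documents the models behind `adaptdose`, the parameters that
matter, and what the synthetic cohort does and does not emulate.

## Geometry and grids

All coordinates are millimetres in patient space, axis order (x, y, z);
grids are axis-aligned with identity orientation (oblique DICOM
orientations are rejected, not resampled, to keep geometry auditable).
A voxel's coordinate is its centre; volumes in cc are
`count · voxel_volume / 1000`. The default synthetic grid uses the
clinical MRI voxel of 1.6 × 1.6 mm in-plane and 3 mm slices on a
20 × 20 × 14.4 cm field of view; the acceptance-scale cohort runs on a
2 mm isotropic grid, which keeps the full 50-fraction simulation around a
minute while leaving the 1-cc metrics stable (a 2 mm voxel is 0.008 cc).

Structures are stacks of closed planar polygons. Rasterisation uses the
even-odd rule on voxel centres; with supersampling factor f (default 2)
each voxel is judged by the majority of an f × f in-plane sub-centre
lattice, and an exact half-coverage tie falls back to the voxel-centre
rule — without the tie-break, inclusive majority voting systematically
inflates areas along straight edges by ~0.25·|cosθ − sinθ| voxels per
unit edge length. Margins, crops and rings use the exact Euclidean
distance transform with anisotropic spacing; boundary voxels at exactly
the margin distance are included (tolerance 1e-9 mm).

## DVH metrics

V-at-dose and D-at-volume are computed from the organ's voxel dose list,
never from a binned curve (the 0.1 Gy default bin width affects plots
only). The dose threshold is inclusive (≥ 33 Gy) by default with a
strict-mode flag; the convention is recorded in every report manifest, and
at floating-point dose values the two differ only on exact ties — the
surrogate planner deliberately clamps to 32.9 Gy so its plans never sit on
the tie. D-at-volume returns the smallest voxel dose whose at-or-above
count fits in the requested volume; if even the hottest tied block
exceeds it (volume below one voxel, or a uniform field), the maximum dose
is returned. Dose fields are resampled to mask grids by trilinear
interpolation; nearest-neighbour is not offered because the analysis
lives in steep-gradient regions next to organs at risk.

The optional 3-cm ring restriction (organ ∩ shell around the target)
bounds every V-metric from above by its unrestricted value. It is ON by
default for cohort summaries and OFF for raw organ metrics; which mode
produced a report is stored in its manifest, since the clinically
reported values are ambiguous between the two.

## Surrogate isotoxic planner

The clinical step-and-shoot IMRT optimiser with Monte-Carlo dose is
replaced by a deterministic construction that reproduces the *constraint
geometry* the analysis depends on — steep gradients abutting GI-OARs —
without modelling deliverable beams:

```
T_opt  = target  minus  (GI-OAR union expanded by 3 mm)
dose(p) = max(background, 50 Gy − g · dist(p, T_opt))
```

with falloff gradient g = 4 Gy/mm by default (steep; realistic SBRT
gradients span roughly 1–5 Gy/mm, and g controls how punishing motion
is). A plan is made isotoxic by clamping, per organ: all above-threshold
organ voxels except the hottest allowed sub-volume are set to
33 − 0.1 Gy, with a feathering cap `32.9 + g·dist` in a 2 mm transition
band outside the organ (other organs and the target are never touched by
the band). Keeping the hottest exactly-1-cc sub-volume makes adapted
plans sit at the constraint boundary, as clinically re-optimised isotoxic
plans do.

Adaptation re-derives `T_opt` on the day's anatomy, re-paints, and clamps
each organ to `min(1 cc, scheduled V33Gy on the same anatomy)`. The
second term encodes re-optimiser organ-sparing priority: an adapted plan
never does worse than the scheduled plan at any organ, even when crop
geometry changes (another organ moving away can otherwise enlarge the
optimisation target near a compliant organ and raise its dose). When an
organ overlaps the prescription region so that clamping sacrifices target
coverage, the conflict is resolved in favour of the organ and flagged in
the plan metadata. The adaptation trigger is: any GI-OAR V33Gy strictly
above 1 cc (the boundary value is compliant), or a re-paint on today's
anatomy gaining ≥ 10 percentage points of target coverage; both reasons
are reported separately.

## Synthetic cohort

The generator replaces unavailable clinical MRIs; its defaults are the
study conditions, not tuning knobs.

*Anatomy.* The target is a perturbed ellipsoid: volume drawn from a
log-normal with median 86 cc truncated to 36–145 cc, random axis ratios,
and low-order (m = 2, 3) angular Fourier perturbations up to 8%; contour
stacks are rescaled once so the analytic stack volume matches the draw.
The four GI-OARs are curved tubes (per-slice near-circular polygons along
a wobbling centreline) arranged at well-separated azimuths with
organ-specific surface gaps to the target: duodenum 0.5–2 mm (so at least
one organ is always within 3 mm of the target, as in the clinical
cohort), stomach 3–9 mm, small bowel 6–14 mm, colon 14–24 mm, and
organ-specific tube radii (8–20 mm). Generated anatomies are validated by
rasterisation (volume in range, duodenum gap ≤ 3 mm) with bounded
retries.

*Motion.* No clinical displacement magnitudes are available, only their
dosimetric consequences, so the model is the simplest stochastic process
able to move organs from their carved low-dose pockets into high-dose
regions: per organ, a rigid translation drawn from an isotropic 3-D
normal, plus a smooth in-plane deformation field (i.i.d. normal node
values on a lattice at the correlation length, trilinearly interpolated
to vertices; self-intersecting results trigger amplitude halving with a
warning, never silent invalid geometry). The target moves only by a
baseline-shift translation, which registration removes. Two parameter
blocks reuse this machinery:

| level | translation σ | deformation amp. | corr. length | target shift σ |
|---|---|---|---|---|
| inter-fraction (day-to-day) | 5 mm | 3 mm | 40 mm | 0 (couch-corrected) |
| intra-fraction (peristalsis) | 3 mm | 2 mm | 30 mm | 2 mm |

The inter-fraction level was chosen once so that a majority of scheduled
plans violate at least one constraint on the day's anatomy (the clinical
cohort adapted 100% of fractions); the intra-fraction level is the
"moderate motion" condition. With the default course (10 patients ×
5 fractions, master seed 1, 2 mm grid) the pipeline yields: scheduled
violations in 72% of fractions, 100% adapted-plan compliance,
post-treatment re-violation in 0–22% of fractions per organ, post ≥
adapted in 70% of organ-fractions, and benefit (post < scheduled among
scheduled-exceeding organ-fractions) in 91% — the directional findings
of the clinical analysis. The synthetic magnitudes are milder than the
clinical cohort's (which saw post-treatment duodenum exceedance of 62%),
so passing tests demonstrate the *ordering* of effects, not clinical
effect sizes.

*Seeds.* Every stream derives from one master seed via
`SeedSequence(master, spawn_key=(patient, fraction, stream))` with
streams 0 = anatomy, 1 = inter-fraction, 2 = intra-fraction, so any case
regenerates in isolation.

*What the generator does not emulate.* Organ wall thickness and lumen,
gastric filling, respiratory motion and gating (the pipeline models only
end-exhale volumetric snapshots), deliverable beam geometry, CT density,
inter-observer contouring variation, and intra-treatment dose
accumulation over deforming anatomy (the three-time-point comparison is
a worst-case snapshot analysis).

## Registration

Post-treatment anatomy is registered to pre-treatment anatomy by a pure
translation aligning the rasterised target centroids (rotation fixed to
identity, matching couch-translation-only localisation). Constructed
shifts are recovered to within one voxel; with zero target baseline
shift the transform is numerically zero and organ displacements pass
through unchanged.

## Summary conventions

Exceedance is strict (> 1.0 cc) because the criterion is compliance with
≤ 1 cc; the boundary value is compliant. Better/worse comparisons are
strict; exact ties (common in coarse-voxel synthetic data, e.g. identical
clamped plans) are counted in a separate tie column rather than as
either outcome. Benefit percentages are undefined (reported NA) for
organs with no scheduled-exceeding fraction. Reported percentages are
rounded half away from zero to integers (23/35 → 66%), with unrounded
values retained in the same tables. Per-patient averages are arithmetic
means over that patient's available fractions; partial courses are
flagged.

## Numerical choices

- EDT distance comparisons include a 1e-9 mm tolerance so boundary
  voxels at exactly the margin are inside.
- The clamp offset ε = 0.1 Gy keeps clamped voxels clear of the
  inclusive-≥ threshold.
- Clamp and summaries use half-voxel slack (1e-12 cc scale) when
  comparing volumes to the constraint to avoid float-equality artefacts.
- Degenerate inputs: empty structure → empty mask with warning; empty
  optimisation target → planning error; empty target coverage → error;
  volume requests beyond the organ → argument error.

## Known limitations

The surrogate painter has no optimiser trade-offs: target coverage is
always 100% inside `T_opt` and falloff is isotropic, so coverage-gain
triggers fire less often than OAR triggers. Tube-shaped organs
underestimate the irregular duodenal C-loop geometry; the clamp-pocket
mechanism (dose pockets exactly at organ positions) is shared with real
isotoxic plans, but real dose pockets are smoother. Cohort percentages
therefore depend on the chosen motion magnitudes and gradient; only the
directional conclusions are generator-independent.
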