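"""DVH metrics against brute-force sort/scan and closed-form oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adaptdose.core import BinaryMask, DoseGrid, ImageGrid3D
from adaptdose.dvh import (
    coverage,
    cumulative_dvh,
    d_at_volume,
    sample_dose,
    v_at_dose,
)

from conftest import random_dose, random_mask


def brute_v_at_dose(doses, vox_cc, thr):
    return sum(1 for d in doses if d >= thr) * vox_cc


def brute_d_at_volume(doses, vox_cc, volume_cc):
    """Exhaustive scan: smallest voxel dose whose >=-count fits in volume_cc,
    else the maximum dose."""
    doses = sorted(doses)
    k = int(np.floor(volume_cc / vox_cc + 1e-12))
    for d in doses:
        if sum(1 for x in doses if x >= d) <= k:
            return d
    return doses[-1]


class TestSampleDose:
    def test_constant_field(self, unit_grid, rng):
        d = DoseGrid(unit_grid, np.full(unit_grid.shape, 50.0))
        pts = rng.uniform(5, 35, size=(20, 3))
        assert np.allclose(sample_dose(d, pts), 50.0)

    def test_linear_field_exact(self, unit_grid, rng):
        """Trilinear interpolation is exact on fields linear in x."""
        x = unit_grid.axis_coords(0)
        dose = np.broadcast_to(
            (2.0 + 0.5 * x)[:, None, None], unit_grid.shape
        ).copy()
        d = DoseGrid(unit_grid, dose)
        pts = rng.uniform(2, 38, size=(50, 3))
        assert np.allclose(sample_dose(d, pts), 2.0 + 0.5 * pts[:, 0])

    def test_voxel_centers_exact_lookup(self, unit_grid, rng):
        d = random_dose(unit_grid, rng)
        idx = rng.integers(0, 40, size=(30, 3))
        pts = unit_grid.index_to_world(idx)
        assert np.allclose(sample_dose(d, pts), d.dose[tuple(idx.T)])

    def test_outside_point_errors_and_clamps(self, unit_grid, rng):
        d = random_dose(unit_grid, rng)
        with pytest.raises(ValueError, match="outside"):
            sample_dose(d, [[100.0, 5.0, 5.0]])
        edge = sample_dose(d, [[100.0, 5.5, 5.5]], out_of_bounds="clamp")
        assert edge[0] == pytest.approx(d.dose[39, 5, 5])


class TestVAtDose:
    def test_uniform_50gy_1000_voxels(self):
        grid = ImageGrid3D((0, 0, 0), (1, 1, 1), (10, 10, 10))
        d = DoseGrid(grid, np.full(grid.shape, 50.0))
        m = BinaryMask(grid, np.ones(grid.shape, bool))
        assert v_at_dose(d, m, 33.0) == pytest.approx(1.0)

    def test_uniform_below_threshold_zero(self):
        grid = ImageGrid3D((0, 0, 0), (1, 1, 1), (10, 10, 10))
        d = DoseGrid(grid, np.full(grid.shape, 10.0))
        m = BinaryMask(grid, np.ones(grid.shape, bool))
        assert v_at_dose(d, m, 33.0) == 0.0

    def test_plane_cut_analytic(self):
        """Dose falling linearly across a box: above-threshold volume equals
        the analytic fraction within one voxel layer."""
        grid = ImageGrid3D((0.5, 0.5, 0.5), (1, 1, 1), (50, 20, 20))
        x = grid.axis_coords(0)
        dose = np.broadcast_to(
            (50.0 - 0.8 * x)[:, None, None], grid.shape
        ).copy()
        d = DoseGrid(grid, dose)
        m = BinaryMask(grid, np.ones(grid.shape, bool))
        # dose >= 33 iff x <= 21.25; box x-extent [0, 50]
        analytic_cc = (21.25 / 50.0) * 50 * 20 * 20 / 1000.0
        layer_cc = 20 * 20 / 1000.0
        assert abs(v_at_dose(d, m, 33.0) - analytic_cc) <= layer_cc

    def test_strict_mode_excludes_exact_threshold(self):
        grid = ImageGrid3D((0, 0, 0), (1, 1, 1), (5, 5, 5))
        d = DoseGrid(grid, np.full(grid.shape, 33.0))
        m = BinaryMask(grid, np.ones(grid.shape, bool))
        assert v_at_dose(d, m, 33.0) == pytest.approx(0.125)
        assert v_at_dose(d, m, 33.0, strict=True) == 0.0

    def test_empty_mask_zero(self, unit_grid, rng):
        d = random_dose(unit_grid, rng)
        m = BinaryMask(unit_grid, np.zeros(unit_grid.shape, bool))
        assert v_at_dose(d, m, 33.0) == 0.0

    def test_negative_threshold_rejected(self, unit_grid, rng):
        with pytest.raises(ValueError):
            v_at_dose(random_dose(unit_grid, rng), random_mask(unit_grid, rng), -1.0)


class TestDAtVolume:
    def test_uniform_field_returns_uniform_dose(self):
        grid = ImageGrid3D((0, 0, 0), (1, 1, 1), (10, 10, 10))
        d = DoseGrid(grid, np.full(grid.shape, 41.5))
        m = BinaryMask(grid, np.ones(grid.shape, bool))
        for v in (0.035, 0.5, 1.0):
            assert d_at_volume(d, m, v) == 41.5

    def test_full_volume_is_min_dose(self, unit_grid, rng):
        d = random_dose(unit_grid, rng)
        m = random_mask(unit_grid, rng)
        assert d_at_volume(d, m, m.volume_cc) == pytest.approx(
            d.dose[m.occupancy].min()
        )

    def test_matches_brute_force_scan(self, unit_grid, rng):
        vox = unit_grid.voxel_volume_cc
        for _ in range(5):
            d = random_dose(unit_grid, rng)
            m = random_mask(unit_grid, rng, p=0.02)
            doses = list(d.dose[m.occupancy])
            for v in (0.035, 0.5, 1.0, 3.0):
                if v <= len(doses) * vox:
                    assert d_at_volume(d, m, v) == pytest.approx(
                        brute_d_at_volume(doses, vox, v)
                    )

    def test_over_volume_rejected(self, unit_grid, rng):
        d = random_dose(unit_grid, rng)
        m = random_mask(unit_grid, rng, p=0.01)
        with pytest.raises(ValueError):
            d_at_volume(d, m, m.volume_cc + 1.0)


class TestCumulativeDVH:
    def test_uniform_step_function(self):
        grid = ImageGrid3D((0, 0, 0), (1, 1, 1), (10, 10, 10))
        d = DoseGrid(grid, np.full(grid.shape, 20.0))
        m = BinaryMask(grid, np.ones(grid.shape, bool))
        c = cumulative_dvh(d, m, bin_width_gy=0.5)
        assert c.cumulative_volume[0] == pytest.approx(1.0)
        below = c.bin_edges <= 20.0
        assert np.allclose(c.cumulative_volume[below], 1.0)
        assert np.allclose(c.cumulative_volume[~below], 0.0)

    def test_empty_mask_all_zero(self, unit_grid, rng):
        d = random_dose(unit_grid, rng)
        m = BinaryMask(unit_grid, np.zeros(unit_grid.shape, bool))
        c = cumulative_dvh(d, m)
        assert np.all(c.cumulative_volume == 0)

    def test_pointwise_matches_v_at_dose(self, unit_grid, rng):
        d = random_dose(unit_grid, rng)
        m = random_mask(unit_grid, rng)
        c = cumulative_dvh(d, m, bin_width_gy=2.5)
        for edge, vol in zip(c.bin_edges, c.cumulative_volume):
            assert vol == pytest.approx(v_at_dose(d, m, edge))

    def test_curve_starts_at_total_volume(self, unit_grid, rng):
        d = random_dose(unit_grid, rng)
        m = random_mask(unit_grid, rng)
        c = cumulative_dvh(d, m)
        assert c.cumulative_volume[0] == pytest.approx(m.volume_cc)


class TestCoverage:
    def test_uniform_prescription_100pct(self, unit_grid, rng):
        d = DoseGrid(unit_grid, np.full(unit_grid.shape, 50.0))
        m = random_mask(unit_grid, rng)
        assert coverage(d, m, 50.0) == 100.0

    def test_below_prescription_0pct(self, unit_grid, rng):
        d = DoseGrid(unit_grid, np.full(unit_grid.shape, 45.0))
        m = random_mask(unit_grid, rng)
        assert coverage(d, m, 50.0) == 0.0

    def test_half_target_plane_cut(self):
        grid = ImageGrid3D((0.5, 0.5, 0.5), (1, 1, 1), (40, 10, 10))
        x = grid.axis_coords(0)
        dose = np.broadcast_to(
            np.where(x < 20.0, 55.0, 10.0)[:, None, None], grid.shape
        ).copy()
        d = DoseGrid(grid, dose)
        m = BinaryMask(grid, np.ones(grid.shape, bool))
        layer_pct = 100.0 / 40
        assert abs(coverage(d, m, 50.0) - 50.0) <= layer_pct

    def test_empty_target_errors(self, unit_grid, rng):
        d = random_dose(unit_grid, rng)
        with pytest.raises(ValueError):
            coverage(d, BinaryMask(unit_grid, np.zeros(unit_grid.shape, bool)), 50.0)


class TestInvariants:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_v_monotone_and_inverse_consistent(self, seed):
        """v_at_dose non-increasing in threshold; d_at_volume non-increasing
        in volume; v(d(v)) <= v on continuous random fields."""
        grid = ImageGrid3D((0, 0, 0), (1, 1, 1), (12, 12, 12))
        r = np.random.default_rng(seed)
        d = DoseGrid(grid, r.uniform(0, 60, grid.shape))
        m = BinaryMask(grid, r.random(grid.shape) < 0.4)
        if not m.occupancy.any():
            return
        thr = np.sort(r.uniform(0, 60, 5))
        vs = [v_at_dose(d, m, t) for t in thr]
        assert all(a >= b for a, b in zip(vs, vs[1:]))
        vols = np.sort(r.uniform(0.001, m.volume_cc, 4))[::-1]
        ds = [d_at_volume(d, m, v) for v in vols]
        assert all(a <= b for a, b in zip(ds, ds[1:]))
        for v in vols:
            assert v_at_dose(d, m, d_at_volume(d, m, v)) <= v + 1e-12

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), c=st.floats(0.2, 4.0))
    def test_dose_scaling_covariance(self, seed, c):
        """Scaling doses by c scales d_at_volume by c and maps
        v_at_dose(t) to v_at_dose(t/c)."""
        grid = ImageGrid3D((0, 0, 0), (1, 1, 1), (10, 10, 10))
        r = np.random.default_rng(seed)
        dose = r.uniform(0, 60, grid.shape)
        m = BinaryMask(grid, r.random(grid.shape) < 0.4)
        if not m.occupancy.any():
            return
        d1, dc = DoseGrid(grid, dose), DoseGrid(grid, c * dose)
        assert d_at_volume(dc, m, 0.05) == pytest.approx(
            c * d_at_volume(d1, m, 0.05)
        )
        t = 33.0
        assert v_at_dose(dc, m, t) == pytest.approx(v_at_dose(d1, m, t / c))

    def test_ring_restriction_never_increases(self, unit_grid, rng):
        d = random_dose(unit_grid, rng)
        m = random_mask(unit_grid, rng)
        restrict = random_mask(unit_grid, rng, p=0.5)
        assert v_at_dose(d, m, 33.0, restrict_mask=restrict) <= v_at_dose(
            d, m, 33.0
        )


def test_resampling_between_grids(rng):
    """V33Gy of a mask on a finer grid against a coarse dose field uses
    trilinear resampling; a constant field is invariant to it."""
    coarse = ImageGrid3D((0, 0, 0), (2, 2, 2), (20, 20, 20))
    fine = ImageGrid3D((0, 0, 0), (1, 1, 1), (39, 39, 39))
    d = DoseGrid(coarse, np.full(coarse.shape, 40.0))
    m = BinaryMask(fine, rng.random(fine.shape) < 0.2)
    assert v_at_dose(d, m, 33.0) == pytest.approx(m.volume_cc)
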