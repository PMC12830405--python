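"""Dose-distribution metrics against brute-force oracles."""

import numpy as np
import pytest

from geldose.metrics import (
    GammaCriteria,
    coefficient_of_variation,
    dose_percentile,
    dvh,
    gamma_index,
    heterogeneity_index,
    isodose_mask,
    line_profile,
    sum_dose_maps,
    voi_stats,
)
from geldose.volumes import ScalarVolume, VOIMask, VolumeError, VoxelGrid

from conftest import full_mask, make_volume


def dose_volume(values, spacing=(1.0, 1.0, 1.0)):
    grid = VoxelGrid(np.shape(values), spacing)
    return ScalarVolume(grid, values, "Gy")


def two_level_volume():
    vals = np.empty((4, 4, 4))
    vals[:2] = 1.0
    vals[2:] = 3.0
    return dose_volume(vals)


class TestVoiStats:
    def test_uniform_field(self):
        vol = dose_volume(np.full((3, 3, 3), 10.0))
        s = voi_stats(vol, full_mask(vol.grid))
        assert s["mean"] == 10.0 and s["sd"] == 0.0 and s["voxel_count"] == 27

    def test_two_level_field(self):
        vol = two_level_volume()
        s = voi_stats(vol, full_mask(vol.grid))
        assert s["mean"] == pytest.approx(2.0)
        assert s["sd"] == pytest.approx(1.0)  # population sd

    def test_random_field_matches_scalar_loop(self, rng):
        vals = rng.uniform(0, 20, (5, 5, 5))
        sel = rng.random((5, 5, 5)) > 0.4
        sel[0, 0, 0] = True
        vol = dose_volume(vals)
        mask = VOIMask(vol.grid, sel, "m")
        s = voi_stats(vol, mask)
        picked = [vals[i] for i in np.ndindex(vals.shape) if sel[i]]
        assert s["mean"] == pytest.approx(np.mean(picked), abs=1e-12)
        assert s["sd"] == pytest.approx(np.std(picked), abs=1e-12)
        assert s["min"] == min(picked) and s["max"] == max(picked)

    def test_empty_mask_rejected(self):
        vol = dose_volume(np.zeros((2, 2, 2)))
        with pytest.raises(VolumeError):
            voi_stats(vol, VOIMask(vol.grid, np.zeros((2, 2, 2), bool), "empty"))


class TestDVH:
    def test_uniform_dose_is_step_function(self):
        vol = dose_volume(np.full((3, 3, 3), 5.0))
        curve = dvh(vol, full_mask(vol.grid), bin_width_gy=1.0)
        assert curve.cum_volume_fraction[0] == 1.0
        below = curve.dose_edges <= 5.0
        np.testing.assert_array_equal(curve.cum_volume_fraction[below], 1.0)
        np.testing.assert_array_equal(curve.cum_volume_fraction[~below], 0.0)

    def test_counts_match_brute_force(self, rng):
        vals = rng.uniform(0, 10, (4, 4, 4))
        vol = dose_volume(vals)
        curve = dvh(vol, full_mask(vol.grid), bin_width_gy=0.5)
        for edge, frac in zip(curve.dose_edges, curve.cum_volume_fraction):
            assert frac == pytest.approx(np.mean(vals >= edge))

    def test_non_increasing_and_terminates_at_zero(self, rng):
        vol = dose_volume(rng.uniform(0, 10, (4, 4, 4)))
        curve = dvh(vol, full_mask(vol.grid), 0.7)
        assert np.all(np.diff(curve.cum_volume_fraction) <= 0)
        assert curve.cum_volume_fraction[-1] == 0.0


class TestPercentilesAndIndices:
    def test_uniform_percentiles_equal_the_dose(self):
        vol = dose_volume(np.full((3, 3, 3), 4.0))
        for x in (2, 50, 98):
            assert dose_percentile(vol, full_mask(vol.grid), x) == 4.0

    def test_median_of_odd_symmetric_set(self):
        # 7 masked voxels with doses 1..7 Gy: D50 is the middle value
        vol = dose_volume(np.array([1, 2, 3, 4, 5, 6, 7, 99], float).reshape(2, 2, 2))
        sel = np.ones((2, 2, 2), bool)
        sel[1, 1, 1] = False
        assert dose_percentile(vol, VOIMask(vol.grid, sel, "m"), 50) == 4.0

    @pytest.mark.parametrize("x", [2.0, 50.0, 98.0])
    def test_random_doses_match_sorted_array_oracle(self, rng, x):
        vals = rng.uniform(0, 30, (100,))
        vol = dose_volume(vals.reshape(4, 5, 5))
        got = dose_percentile(vol, full_mask(vol.grid), x)
        # oracle: descending sort, linear interpolation at rank (x/100)(n-1)
        desc = np.sort(vals)[::-1]
        pos = x / 100.0 * (len(vals) - 1)
        lo, hi = int(np.floor(pos)), int(np.ceil(pos))
        expect = desc[lo] + (pos - lo) * (desc[hi] - desc[lo])
        assert got == pytest.approx(expect, abs=1e-12)

    def test_hi_zero_for_uniform_and_scale_invariant(self, rng):
        uni = dose_volume(np.full((3, 3, 3), 7.0))
        assert heterogeneity_index(uni, full_mask(uni.grid)) == 0.0
        vals = rng.uniform(1, 20, (4, 4, 4))
        a = heterogeneity_index(dose_volume(vals), full_mask(VoxelGrid((4, 4, 4), (1, 1, 1))))
        b = heterogeneity_index(dose_volume(3.5 * vals), full_mask(VoxelGrid((4, 4, 4), (1, 1, 1))))
        assert a == pytest.approx(b, rel=1e-12)

    def test_hi_two_level_field_from_oracle(self):
        vol = two_level_volume()
        mask = full_mask(vol.grid)
        vals = vol.values.ravel()
        desc = np.sort(vals)[::-1]

        def d_x(x):
            pos = x / 100 * (len(vals) - 1)
            lo, hi = int(np.floor(pos)), int(np.ceil(pos))
            return desc[lo] + (pos - lo) * (desc[hi] - desc[lo])

        expect = (d_x(2) - d_x(98)) / d_x(50)
        assert heterogeneity_index(vol, mask) == pytest.approx(expect, rel=1e-12)

    def test_cv_two_level_field(self):
        vol = two_level_volume()
        assert coefficient_of_variation(vol, full_mask(vol.grid)) == pytest.approx(0.5)

    def test_cv_scale_invariant_and_zero_iff_uniform(self, rng):
        vals = rng.uniform(1, 10, (3, 3, 3))
        grid = VoxelGrid((3, 3, 3), (1, 1, 1))
        a = coefficient_of_variation(dose_volume(vals), full_mask(grid))
        b = coefficient_of_variation(dose_volume(2.0 * vals), full_mask(grid))
        assert a == pytest.approx(b, rel=1e-12)
        assert a > 0
        assert coefficient_of_variation(dose_volume(np.full((3, 3, 3), 2.0)),
                                        full_mask(grid)) == 0.0


class TestProfileAndIsodose:
    def test_constant_volume_constant_profile(self):
        vol = dose_volume(np.full((6, 6, 6), 3.0))
        dist, vals = line_profile(vol, (0, 2, 2), (5, 2, 2), step_mm=0.5)
        np.testing.assert_allclose(vals, 3.0)
        assert dist[0] == 0.0 and dist[-1] == pytest.approx(5.0)

    def test_axis_aligned_nearest_returns_raster(self, rng):
        vals = rng.uniform(0, 10, (6, 4, 4))
        vol = dose_volume(vals)
        dist, got = line_profile(vol, (0, 1, 2), (5, 1, 2), step_mm=1.0,
                                 interpolation="nearest")
        np.testing.assert_allclose(got, vals[:, 1, 2])

    def test_linear_gradient_sampled_exactly_with_trilinear(self):
        grid = VoxelGrid((8, 8, 8), (2.0, 2.0, 2.0), (0.0, 0.0, 0.0))
        X, Y, Z = np.meshgrid(*grid.coordinate_axes(), indexing="ij")
        vol = ScalarVolume(grid, 1.0 + 0.5 * X + 0.25 * Y, "Gy")
        p0, p1 = np.array([2.0, 2.0, 4.0]), np.array([12.0, 10.0, 4.0])
        dist, got = line_profile(vol, p0, p1, step_mm=0.7, interpolation="trilinear")
        direction = (p1 - p0) / np.linalg.norm(p1 - p0)
        pts = p0[None] + dist[:, None] * direction
        expect = 1.0 + 0.5 * pts[:, 0] + 0.25 * pts[:, 1]
        np.testing.assert_allclose(got, expect, atol=1e-9)

    def test_endpoint_outside_volume_rejected(self):
        vol = dose_volume(np.zeros((4, 4, 4)))
        with pytest.raises(VolumeError):
            line_profile(vol, (0, 0, 0), (10, 0, 0))

    def test_isodose_levels_nest(self, rng):
        vol = dose_volume(rng.uniform(0, 10, (5, 5, 5)))
        assert isodose_mask(vol, 0.0).membership.all()
        assert not isodose_mask(vol, 11.0).membership.any()
        lo, hi = isodose_mask(vol, 3.0), isodose_mask(vol, 7.0)
        assert np.all(~hi.membership | lo.membership)  # hi subset of lo


class TestSumDoseMaps:
    def test_published_sphere_means_sum_exactly(self):
        a = dose_volume(np.full((3, 3, 3), 9.71))
        b = dose_volume(np.full((3, 3, 3), 9.83))
        total = sum_dose_maps([a, b])
        np.testing.assert_allclose(total.values, 19.54, rtol=1e-12)

    def test_zero_map_is_identity(self, rng):
        a = dose_volume(rng.uniform(0, 5, (3, 3, 3)))
        z = dose_volume(np.zeros((3, 3, 3)))
        np.testing.assert_array_equal(sum_dose_maps([a, z]).values, a.values)

    def test_voi_mean_is_linear_in_summation(self, rng):
        grid = VoxelGrid((4, 4, 4), (1, 1, 1))
        a = dose_volume(rng.uniform(0, 5, (4, 4, 4)))
        b = dose_volume(rng.uniform(0, 5, (4, 4, 4)))
        mask = full_mask(grid)
        total = sum_dose_maps([a, b])
        assert voi_stats(total, mask)["mean"] == pytest.approx(
            voi_stats(a, mask)["mean"] + voi_stats(b, mask)["mean"], rel=1e-12
        )

    def test_grid_mismatch_rejected(self):
        a = dose_volume(np.zeros((3, 3, 3)))
        b = dose_volume(np.zeros((3, 3, 3)), spacing=(2, 2, 2))
        with pytest.raises(VolumeError):
            sum_dose_maps([a, b])


def gamma_exhaustive_oracle(ref, ev, spacing, dose_tol, dta, cutoff_abs):
    """Brute-force gamma: full search over all evaluated voxels, no shortcuts."""
    shape = ref.shape
    coords = np.stack(
        np.meshgrid(*[np.arange(n) * s for n, s in zip(shape, spacing)], indexing="ij"),
        axis=-1,
    ).reshape(-1, 3)
    ref_flat, ev_flat = ref.ravel(), ev.ravel()
    out = np.full(ref_flat.shape, np.nan)
    for i in range(ref_flat.size):
        if ref_flat[i] < cutoff_abs:
            continue
        d2 = ((coords - coords[i]) ** 2).sum(axis=1) / dta**2
        dd2 = ((ev_flat - ref_flat[i]) / dose_tol) ** 2
        out[i] = np.sqrt((d2 + dd2).min())
    return out.reshape(shape)


class TestGammaIndex:
    def test_self_comparison_passes_everywhere(self, rng):
        vol = dose_volume(rng.uniform(1, 10, (6, 6, 6)))
        gmap, rate = gamma_index(vol, vol)
        assert rate == 100.0
        finite = np.isfinite(gmap)
        assert np.all(gmap[finite] == 0.0)

    def test_uniform_offset_at_exact_dose_tolerance_is_boundary_pass(self):
        ref = dose_volume(np.full((4, 4, 4), 10.0))
        ev = dose_volume(np.full((4, 4, 4), 10.3))  # +3% of the 10 Gy global max
        gmap, rate = gamma_index(ref, ev, GammaCriteria(dose_tol_percent=3.0))
        np.testing.assert_allclose(gmap, 1.0, rtol=1e-12)
        assert rate == 100.0

    @pytest.mark.parametrize("shape,spacing", [((8, 8, 8), (2.0, 2.0, 2.0)),
                                               ((16, 16, 16), (1.0, 1.5, 2.0))])
    def test_random_pair_matches_exhaustive_oracle(self, rng, shape, spacing):
        ref_vals = rng.uniform(0, 10, shape)
        ev_vals = np.clip(ref_vals + rng.normal(0, 0.8, shape), 0, None)
        ref = dose_volume(ref_vals, spacing)
        ev = dose_volume(ev_vals, spacing)
        crit = GammaCriteria(dose_tol_percent=3.0, dta_mm=3.0, low_dose_cutoff_fraction=0.1)
        gmap, rate = gamma_index(ref, ev, crit)
        oracle = gamma_exhaustive_oracle(
            ref_vals, ev_vals, spacing, 0.03 * ref_vals.max(), 3.0,
            0.1 * ref_vals.max(),
        )
        np.testing.assert_allclose(gmap, oracle, atol=1e-9, equal_nan=True)
        finite = np.isfinite(oracle)
        assert rate == pytest.approx(100.0 * np.mean(oracle[finite] <= 1.0 + 1e-12))

    def test_low_dose_voxels_excluded(self):
        vals = np.full((4, 4, 4), 0.5)
        vals[2:, :, :] = 10.0
        ref = dose_volume(vals)
        gmap, _ = gamma_index(ref, ref)
        assert np.all(np.isnan(gmap[:2]))
        assert np.all(np.isfinite(gmap[2:]))

    def test_zero_reference_rejected(self):
        z = dose_volume(np.zeros((3, 3, 3)))
        with pytest.raises(VolumeError):
            gamma_index(z, z)
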