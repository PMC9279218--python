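"""Blanket iteration, surface measures, FD fits, local and global maps."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from fractalct.fractal import (
    SUPPORT_DIM,
    blanket_iterate,
    default_global_scales,
    fit_fd,
    global_fd,
    local_fd_map,
    surface_measure,
    surface_measures,
)
from fractalct.reference import local_fd_map_naive
from fractalct.types import PhaseStack, RegionMask

finite_textures = hnp.arrays(
    dtype=np.float64,
    shape=st.tuples(*(st.integers(2, 4),) * 4),
    elements=st.floats(-100, 100, allow_nan=False, width=32),
)


class TestBlanketIterate:
    def test_flat_texture_closed_form(self):
        """u_ε = c+ε, b_ε = c−ε on a constant field, so u−b = 2ε."""
        tex = np.full((5, 5, 5, 3), 7.0)
        for pair in blanket_iterate(tex, 3):
            assert np.array_equal(pair.upper, tex + pair.epsilon)
            assert np.array_equal(pair.lower, tex - pair.epsilon)

    def test_impulse_spreads_to_direct_neighbours(self):
        """After one step, u equals the impulse height at its 8 direct 4D
        neighbours (hand-executed update on a 3×3×3×3 block)."""
        tex = np.zeros((3, 3, 3, 3))
        c = (1, 1, 1, 1)
        tex[c] = 10.0
        pair = next(blanket_iterate(tex, 1))
        for axis in range(4):
            for step in (-1, 1):
                n = list(c)
                n[axis] += step
                assert pair.upper[tuple(n)] == 10.0
        # diagonal neighbour is NOT reached in one step
        assert pair.upper[(0, 0, 1, 1)] == 1.0
        assert pair.upper[c] == 11.0  # impulse itself raised by 1

    @given(finite_textures)
    def test_sandwich_and_monotonicity(self, tex):
        """upper₂ ≥ upper₁ ≥ texture ≥ lower₁ ≥ lower₂, voxelwise."""
        pairs = list(blanket_iterate(tex, 2))
        u1, b1 = pairs[0].upper, pairs[0].lower
        u2, b2 = pairs[1].upper, pairs[1].lower
        assert np.all(u2 >= u1) and np.all(u1 >= tex)
        assert np.all(tex >= b1) and np.all(b1 >= b2)

    def test_rejects_non_finite(self):
        tex = np.zeros((3, 3, 3, 3))
        tex[0, 0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            next(blanket_iterate(tex, 1))


class TestSurfaceMeasure:
    def test_flat_region_measure_is_voxel_count_at_every_scale(self):
        tex = np.full((4, 4, 4, 2), 3.0)
        areas = surface_measures(tex, (1, 2, 3))
        assert np.allclose(areas, tex.size)

    def test_region_restriction(self):
        tex = np.full((4, 4, 4, 2), 1.0)
        region = np.zeros_like(tex, dtype=bool)
        region[:2] = True
        areas = surface_measures(tex, (1, 2), region)
        assert np.allclose(areas, region.sum())

    def test_single_pair_api_needs_predecessor(self):
        pairs = list(blanket_iterate(np.zeros((3, 3, 3, 2)), 2))
        assert surface_measure(pairs[0]) == pytest.approx(pairs[0].thickness().sum() / 2)
        with pytest.raises(ValueError, match="previous"):
            surface_measure(pairs[1])
        assert surface_measure(pairs[1], previous=pairs[0]) > 0

    def test_checkerboard_matches_naive_reference(self):
        """2×2×2×2 alternating block: fast path equals the windowed naive
        implementation, which brute-forces the update rule voxel by voxel."""
        idx = np.indices((2, 2, 2, 2)).sum(axis=0)
        tex = (idx % 2).astype(np.float64)
        stack = PhaseStack(tex.repeat(3, 0).repeat(3, 1).repeat(3, 2), (1, 1, 1),
                           ("unenhanced", "portal_venous"))
        fast = local_fd_map(stack, window_radius=2, scales=(1, 2))
        naive = local_fd_map_naive(stack, 2, (1, 2))
        np.testing.assert_allclose(fast.values, naive.values, atol=1e-10)


class TestFitFD:
    def test_constant_areas_give_support_dimension(self):
        fit = fit_fd([1, 2, 3], [100.0, 100.0, 100.0])
        assert fit.fd == 4.0
        assert fit.slope == 0.0
        assert fit.fit_r2 == 1.0
        assert not fit.clamped

    def test_inverse_power_law_gives_maximal_dimension(self):
        scales = np.array([1, 2, 3, 4])
        fit = fit_fd(scales, 1000.0 / scales)
        assert fit.fd == pytest.approx(5.0)

    def test_out_of_range_slope_is_clamped_and_flagged(self):
        scales = np.array([1, 2, 4])
        fit = fit_fd(scales, 100.0 * scales.astype(float) ** -1.5)
        assert fit.fd == 5.0 and fit.clamped

    def test_rejects_degenerate_input(self):
        with pytest.raises(ValueError):
            fit_fd([1], [10.0])
        with pytest.raises(ValueError):
            fit_fd([1, 2], [10.0, -1.0])


class TestLocalFDMap:
    def test_flat_stack_maps_to_exactly_four(self, flat_stack):
        m = local_fd_map(flat_stack)
        assert np.all(m.values == 4.0)
        assert m.clamped_fraction == 0.0

    def test_values_bounded_on_adversarial_random_stack(self, rng):
        stack = PhaseStack(rng.uniform(-1000, 1000, (10, 10, 10, 3)), (1, 1, 1))
        m = local_fd_map(stack)
        assert np.all(m.values >= 4.0) and np.all(m.values <= 5.0)
        assert 0.0 <= m.clamped_fraction <= 1.0

    def test_gray_shift_invariance(self, rng):
        vox = rng.normal(0, 30, (6, 6, 6, 3))
        m1 = local_fd_map(PhaseStack(vox, (1, 1, 1)))
        m2 = local_fd_map(PhaseStack(vox + 250.0, (1, 1, 1)))
        np.testing.assert_allclose(m1.values, m2.values, atol=1e-9)

    def test_noise_region_reads_more_chaotic_than_flat_surround(self, rng):
        vox = np.full((16, 16, 8, 3), 50.0)
        vox[4:12, 4:12, 2:6, :] += rng.uniform(-20, 20, (8, 8, 4, 3))
        m = local_fd_map(PhaseStack(vox, (1, 1, 1)))
        inside = m.values[5:11, 5:11, 3:5]
        outside = m.values[:3, :3, :]
        assert inside.mean() > outside.mean()

    def test_window_must_cover_scales(self, flat_stack):
        with pytest.raises(ValueError, match="window_radius"):
            local_fd_map(flat_stack, window_radius=2, scales=(1, 2, 3))

    def test_matches_naive_windowed_reference(self, rng):
        """Exact agreement with the per-window naive implementation."""
        stack = PhaseStack(rng.uniform(0, 100, (5, 5, 5, 3)), (1, 1, 1))
        fast = local_fd_map(stack, window_radius=3, scales=(1, 2, 3))
        naive = local_fd_map_naive(stack, 3, (1, 2, 3))
        np.testing.assert_allclose(fast.values, naive.values, atol=1e-10)
        assert fast.clamped_fraction == naive.clamped_fraction


class TestGlobalFD:
    def test_flat_roi_is_exactly_four_with_perfect_fit(self, flat_stack):
        roi = RegionMask(np.ones((8, 8, 8), bool), (1, 1, 1))
        res = global_fd(flat_stack, roi, scales=(1, 2, 3))
        assert res.fd == 4.0
        assert res.fit_r2 == 1.0

    def test_first_scale_measure_equals_roi_count_on_flat_stack(self, flat_stack):
        roi = np.zeros((8, 8, 8), bool)
        roi[2:5, 2:5, 2:5] = True
        res = global_fd(flat_stack, RegionMask(roi, (1, 1, 1)), scales=(1, 2))
        assert np.exp(res.log_areas[0]) == pytest.approx(roi.sum())

    def test_empty_roi_rejected(self, flat_stack):
        with pytest.raises(ValueError, match="empty"):
            global_fd(flat_stack, RegionMask(np.zeros((8, 8, 8), bool), (1, 1, 1)))

    def test_default_scales_track_roi_extent(self):
        roi = np.zeros((40, 40, 40), bool)
        roi[10:30, 10:30, 10:16] = True  # smallest extent 6
        scales = default_global_scales(RegionMask(roi, (1, 1, 1)))
        assert scales == (1, 2, 3)

    def test_monotone_chaos_response(self):
        """Global FD is non-decreasing in additive noise amplitude."""
        base = np.full((16, 16, 16, 3), 50.0)
        roi = RegionMask(np.ones((16, 16, 16), bool), (1, 1, 1))
        fds = []
        for amp in (0.0, 5.0, 20.0):
            fd_per_seed = []
            for seed in range(5):
                noise = amp * np.random.default_rng(seed).standard_normal(base.shape)
                stack = PhaseStack(base + noise, (1, 1, 1))
                fd_per_seed.append(global_fd(stack, roi, scales=(1, 2, 3, 4)).fd)
            fds.append(np.mean(fd_per_seed))
        assert fds[0] <= fds[1] <= fds[2]

    def test_fbm_dimension_recovery_midpoint(self):
        """Spot-check 5 − H recovery at H = 0.5 (full sweep in acceptance)."""
        from fractalct.phantom import make_fbm_field

        shape = (32, 32, 32, 8)
        roi = RegionMask(np.ones(shape[:3], bool), (1, 1, 1))
        labels = tuple(f"p{i}" for i in range(8))
        fds = [
            global_fd(
                PhaseStack(make_fbm_field(shape, 0.5, s, increment_sd=60.0), (1, 1, 1), labels),
                roi,
                scales=tuple(range(1, 9)),
            ).fd
            for s in range(3)
        ]
        assert abs(np.mean(fds) - 4.5) < 0.15
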