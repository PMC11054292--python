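"""Calibration-pattern generator and sub-pixel localizer."""

import numpy as np
import pytest

from widefield_track3d.config import OpticalConfig
from widefield_track3d.simulate import (
    DegenerateImageError,
    bead_pattern_noise_free,
    build_calibration_library,
    load_library,
    make_z_grid,
    radial_symmetry_center,
    save_library,
    simulate_bead_pattern,
    symmetry_objective,
)


def ncc(a, b):
    a = a - a.mean()
    b = b - b.mean()
    return float((a * b).sum() / np.sqrt((a * a).sum() * (b * b).sum()))


def second_moment(img, center):
    yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
    w = img - img.min()
    return float((w * ((xx - center[0]) ** 2 + (yy - center[1]) ** 2)).sum() / w.sum())


class TestZGrid:
    @pytest.mark.parametrize(
        "zmin,zmax,step,n,first,last",
        [
            (-10.0, 10.0, 0.05, 400, -10.0, 9.95),  # the full calibration scan
            (0.0, 1.0, 0.5, 2, 0.0, 0.5),
            (-1.0, 1.0, 0.05, 40, -1.0, 0.95),
        ],
    )
    def test_counts_and_endpoints(self, zmin, zmax, step, n, first, last):
        grid = make_z_grid(zmin, zmax, step)
        assert len(grid) == n
        assert grid[0] == pytest.approx(first)
        assert grid[-1] == pytest.approx(last)
        assert np.allclose(np.diff(grid), step)

    def test_non_divisible_range_names_remainder(self):
        with pytest.raises(ValueError, match="remainder"):
            make_z_grid(0.0, 1.0, 0.3)

    def test_enumeration_oracle(self):
        # grid by repeated addition, stopping strictly below z_max
        grid = make_z_grid(-1.0, 1.0, 0.05)
        z, expected = -1.0, []
        while z < 1.0 - 1e-12:
            expected.append(z)
            z += 0.05
        assert np.allclose(grid, expected)


class TestBeadPattern:
    def test_centroid_at_center_in_focus(self, small_bead):
        img, center = bead_pattern_noise_free(small_bead, 0.0)
        yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
        w = img - img.min()
        cx = (w * xx).sum() / w.sum()
        cy = (w * yy).sum() / w.sum()
        assert abs(cx - center[0]) < 1e-6 and abs(cy - center[1]) < 1e-6

    def test_above_below_focus_distinguishable(self, small_bead):
        plus, _ = bead_pattern_noise_free(small_bead, 5.0)
        minus, _ = bead_pattern_noise_free(small_bead, -5.0)
        assert ncc(plus, minus) < 0.99

    def test_ring_growth_with_defocus(self, big_bead):
        near, c = bead_pattern_noise_free(big_bead, 2.0)
        far, _ = bead_pattern_noise_free(big_bead, 8.0)
        assert second_moment(far, c) >= second_moment(near, c)

    @pytest.mark.parametrize("sign", [1, -1])
    def test_second_moment_monotone_in_abs_z(self, beads, sign):
        for bead in beads:
            prev = -np.inf
            for z in np.arange(0.0, 10.01, 0.5):
                img, c = bead_pattern_noise_free(bead, sign * z)
                mom = second_moment(img, c)
                assert mom >= prev - 1e-9, f"{bead.label} at z={sign*z}"
                prev = mom

    def test_sign_identifiability_beats_axial_neighbor(self, small_bead):
        # mirrored pattern must look less like z than the next grid position does
        for z in np.arange(1.0, 10.01, 1.0):
            pz, _ = bead_pattern_noise_free(small_bead, z)
            mz, _ = bead_pattern_noise_free(small_bead, -z)
            nz, _ = bead_pattern_noise_free(small_bead, min(z + 0.05, 10.0))
            assert ncc(pz, mz) < ncc(pz, nz)

    def test_z_out_of_range_rejected(self, small_bead):
        with pytest.raises(ValueError, match="outside"):
            simulate_bead_pattern(small_bead, 11.0, OpticalConfig())

    def test_in_focus_most_compact(self, small_bead):
        moments = []
        for z in (-1.0, -0.5, 0.0, 0.5, 1.0):
            img, c = bead_pattern_noise_free(small_bead, z)
            moments.append(second_moment(img, c))
        assert np.argmin(moments) == 2


class TestCalibrationLibrary:
    def test_mini_library_size_and_grid(self, mini_lib):
        assert len(mini_lib) == 2 * 8
        assert np.allclose(np.diff(mini_lib.z_grid), 0.5)

    def test_count_is_classes_times_grid(self, beads):
        cfg = OpticalConfig(z_min_um=-1.0, z_max_um=1.0, z_step_um=0.1)
        lib = build_calibration_library(beads, cfg)
        assert len(lib) == len(beads) * 20

    def test_empty_class_list_rejected(self):
        with pytest.raises(ValueError):
            build_calibration_library([], OpticalConfig())

    def test_deterministic_rebuild(self, beads):
        cfg = OpticalConfig(z_min_um=-1.0, z_max_um=1.0, z_step_um=0.5, seed=3)
        a = build_calibration_library(beads, cfg)
        b = build_calibration_library(beads, cfg)
        for key in a.patches:
            assert np.array_equal(a.patches[key].pixels, b.patches[key].pixels)
            assert a.patches[key].center == b.patches[key].center

    def test_save_load_roundtrip(self, mini_lib, tmp_path):
        save_library(mini_lib, tmp_path / "lib")
        loaded = load_library(tmp_path / "lib")
        assert len(loaded) == len(mini_lib)
        key = ("small", 3)
        # 16-bit quantization: pixel error bounded by one gray level
        assert np.abs(loaded.patches[key].pixels - mini_lib.patches[key].pixels).max() <= 1.0 / 65535 + 1e-7
        assert loaded.patches[key].center == pytest.approx(mini_lib.patches[key].center)


class TestRadialSymmetryCenter:
    def test_recovers_gaussian_center_on_grid(self):
        yy, xx = np.mgrid[0:41, 0:41].astype(float)
        spot = np.exp(-((xx - 20.0) ** 2 + (yy - 20.0) ** 2) / (2 * 9.0))
        assert radial_symmetry_center(spot) == pytest.approx((20.0, 20.0), abs=1e-3)

    def test_recovers_offcenter_gaussian(self):
        yy, xx = np.mgrid[0:41, 0:41].astype(float)
        spot = np.exp(-((xx - 17.30) ** 2 + (yy - 21.80) ** 2) / (2 * 9.0))
        assert radial_symmetry_center(spot) == pytest.approx((17.30, 21.80), abs=0.05)

    def test_monte_carlo_under_noise(self, small_bead, rng):
        img, truth = bead_pattern_noise_free(small_bead, 3.0, (0.25, -0.4))
        errs = []
        for _ in range(200):
            noisy = np.clip(img + rng.normal(0, 0.02, img.shape), 0, 1).astype(np.float32)
            est = radial_symmetry_center(noisy)
            errs.append(np.hypot(est[0] - truth[0], est[1] - truth[1]))
        assert np.mean(errs) < 0.5

    def test_uniform_image_degenerate(self):
        with pytest.raises(DegenerateImageError):
            radial_symmetry_center(np.full((9, 9), 0.5))

    def test_too_small_grid_rejected(self):
        with pytest.raises(ValueError):
            radial_symmetry_center(np.zeros((4, 4)))

    def test_matches_exhaustive_grid_search(self, beads, rng):
        """Closed-form solution vs brute-force 0.01-px minimization of the same objective."""
        for i in range(20):
            bead = beads[i % 2]
            z = float(rng.uniform(-9, 9))
            shift = tuple(rng.uniform(-0.45, 0.45, 2))
            img, _ = bead_pattern_noise_free(bead, z, shift)
            xc, yc = radial_symmetry_center(img)
            # coarse pixel-level search over the whole grid...
            n = img.shape[0]
            coarse = np.array([(x, y) for x in range(1, n - 1, 2) for y in range(1, n - 1, 2)], float)
            obj = symmetry_objective(img, coarse)
            x0, y0 = coarse[np.argmin(obj)]
            # ...then exhaustive 0.01-px refinement around the coarse minimum
            gx = np.arange(x0 - 1.5, x0 + 1.5, 0.01)
            gy = np.arange(y0 - 1.5, y0 + 1.5, 0.01)
            fine = np.array([(x, y) for x in gx for y in gy])
            obj = symmetry_objective(img, fine)
            bx, by = fine[np.argmin(obj)]
            assert np.hypot(bx - xc, by - yc) < 0.02


class TestGridProperties:
    """Property: the grid builder conserves counts and spacing for any valid config."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        z0=st.floats(-50, 49, allow_nan=False),
        span_steps=st.integers(1, 2000),
        step=st.sampled_from([0.05, 0.1, 0.25, 0.5, 1.0]),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_count_and_uniform_spacing(self, z0, span_steps, step):
        z1 = z0 + span_steps * step
        grid = make_z_grid(z0, z1, step)
        assert len(grid) == span_steps
        assert grid[0] == pytest.approx(z0)
        assert np.allclose(np.diff(grid), step, atol=1e-9)
        assert grid[-1] < z1
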