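"""Cube simulation: determinism, noise statistics, scanning modes, artefacts."""
import numpy as np
import pytest

import colposim as cs


@pytest.fixture(scope="module")
def system():
    return cs.clinical_dual_lctf()


@pytest.fixture(scope="module")
def profile(system):
    return cs.ExposureProfile.constant(system.grid, 100.0)


class TestSpectralScan:
    def test_noiseless_cube_equals_rounded_expected_dn(self, system, profile):
        scene = cs.make_flat_scene(system.grid, 0.4, rows=4, cols=4)
        cube = cs.simulate_cube(scene, system, profile, seed=0, noise=False)
        for b in (0, 50, 108):
            expected = np.rint(
                cs.expected_dn(0.4, system, system.grid.wavelengths[b], 100.0)
            )
            assert np.all(cube.data[:, :, b] == expected)

    def test_same_seed_bit_identical(self, system, profile):
        scene = cs.make_flat_scene(system.grid, 0.6, rows=6, cols=6)
        a = cs.simulate_cube(scene, system, profile, seed=9)
        b = cs.simulate_cube(scene, system, profile, seed=9)
        assert np.array_equal(a.data, b.data)

    def test_different_seed_differs(self, system, profile):
        scene = cs.make_flat_scene(system.grid, 0.6, rows=6, cols=6)
        a = cs.simulate_cube(scene, system, profile, seed=9)
        b = cs.simulate_cube(scene, system, profile, seed=10)
        assert not np.array_equal(a.data, b.data)

    def test_mean_dn_within_3se_of_expected(self, system, profile):
        scene = cs.make_flat_scene(system.grid, 0.5, rows=50, cols=50)
        cube = cs.simulate_cube(scene, system, profile, seed=4)
        band = 20
        lam = system.grid.wavelengths[band]
        expected = cs.expected_dn(0.5, system, lam, 100.0)
        se = np.sqrt(system.noise_var_dn(0.5, lam, 100.0) / 2500)
        assert abs(cube.data[:, :, band].mean() - expected) < 3 * se

    def test_grid_mismatch_rejected(self, system, profile):
        other = cs.make_grid(650, 1100, 5, "half_open")
        scene = cs.make_flat_scene(other, 0.5, rows=4, cols=4)
        with pytest.raises(ValueError, match="grid"):
            cs.simulate_cube(scene, system, profile, seed=0)


class TestSpatioSpectralScan:
    def test_zero_motion_noiseless_equals_spectral_scan(self, system, profile):
        scene = cs.make_rezchecker_scene(system.grid)
        static = cs.simulate_cube(scene, system, profile, seed=2, noise=False)
        span = cs.simulate_spatioscan_cube(
            scene, system, profile, cs.MotionModel(0.0), seed=2, noise=False
        )
        assert np.array_equal(static.data, span.data)

    def test_zero_motion_same_seed_bit_identical_with_noise(self, system, profile):
        scene = cs.make_flat_scene(system.grid, 0.5, rows=8, cols=8)
        static = cs.simulate_cube(scene, system, profile, seed=3)
        span = cs.simulate_spatioscan_cube(
            scene, system, profile, cs.MotionModel(0.0), seed=3
        )
        assert np.array_equal(static.data, span.data)

    def test_constant_drift_displaces_edge_by_shift_between_bands(self, system):
        # vertical step edge: left half bright, right half dark
        grid = system.grid
        bright = cs.Spectrum(grid, np.full(grid.n_bands, 0.8))
        dark = cs.Spectrum(grid, np.full(grid.n_bands, 0.1))
        scene = cs.SceneTarget(
            16, 40, grid,
            [cs.Patch("l", 0, 0, 16, 20, bright), cs.Patch("r", 0, 20, 16, 20, dark)],
        )
        prof = cs.ExposureProfile.constant(grid, 100.0)
        shift = 3
        cube = cs.simulate_spatioscan_cube(
            scene, system, prof, cs.MotionModel(float(shift)), seed=0, noise=False
        )

        def edge_col(band, row=0):
            # bright-to-dark transition (most negative difference); the
            # wrap-around edge introduced by the periodic shift is ignored
            line = cube.data[row, :, band].astype(float)
            return int(np.argmin(np.diff(line)))

        for b in range(4):
            assert edge_col(b + 1) - edge_col(b) == shift

    def test_interband_rmse_increases_with_motion_amplitude(self, system, profile):
        scene = cs.make_rezchecker_scene(system.grid)
        means = []
        for amp in (0.0, 1.0, 2.0, 4.0):
            cube = cs.simulate_spatioscan_cube(
                scene, system, profile, cs.MotionModel(amp), seed=6
            )
            means.append(cs.interband_rmse(cube).mean_pct)
        assert means[0] < means[1] < means[2] < means[3]

    def test_random_walk_schedule_is_seeded(self, system, profile):
        scene = cs.make_flat_scene(system.grid, 0.5, rows=8, cols=8)
        m = cs.MotionModel(2.0, schedule="random_walk")
        a = cs.simulate_spatioscan_cube(scene, system, profile, m, seed=4)
        b = cs.simulate_spatioscan_cube(scene, system, profile, m, seed=4)
        assert np.array_equal(a.data, b.data)


class TestFilterTransition:
    def test_magnitude_one_is_identity(self, system, profile):
        scene = cs.make_flat_scene(system.grid, 0.5, rows=4, cols=4)
        cube = cs.simulate_cube(scene, system, profile, seed=1)
        out = cs.inject_filter_transition(cube, (720, 740), 1.0)
        assert np.array_equal(out.data, cube.data)

    def test_perturbation_is_band_local(self, system, profile):
        scene = cs.make_flat_scene(system.grid, 0.5, rows=4, cols=4)
        cube = cs.simulate_cube(scene, system, profile, seed=1, noise=False)
        out = cs.inject_filter_transition(cube, (720, 740), 1.2)
        mask = system.grid.mask_between(720, 740)
        assert np.array_equal(out.data[:, :, ~mask], cube.data[:, :, ~mask])
        assert np.all(out.data[:, :, mask] >= cube.data[:, :, mask])
        assert out.metadata["transition_bands"] == list(np.flatnonzero(mask))

    def test_calibrated_flat_target_shows_bump_only_in_flagged_bands(
        self, system, profile
    ):
        scene = cs.make_flat_scene(system.grid, 0.5, rows=12, cols=12)
        raw = cs.simulate_cube(scene, system, profile, seed=8)
        raw = cs.inject_filter_transition(raw, (720, 740), 1.2)
        white = cs.simulate_cube(
            cs.make_flat_scene(system.grid, 0.95, 12, 12), system, profile, seed=9
        )
        dark = cs.simulate_cube(
            cs.make_flat_scene(system.grid, 0.0, 12, 12), system, profile, seed=10
        )
        refl = cs.calibrate_reflectance(raw, white, dark, white_reflectance=0.95)
        spec = refl.roi_mean(cs.RegionOfInterest(6, 6, 10)).values
        mask = system.grid.mask_between(720, 740)
        assert np.all(spec[mask] > 0.55)
        assert np.all(np.abs(spec[~mask] - 0.5) < 0.05)

    def test_range_outside_grid_rejected(self, system, profile):
        scene = cs.make_flat_scene(system.grid, 0.5, rows=4, cols=4)
        cube = cs.simulate_cube(scene, system, profile, seed=1)
        with pytest.raises(ValueError, match="outside"):
            cs.inject_filter_transition(cube, (1200, 1300), 1.2)
        with pytest.raises(ValueError):
            cs.inject_filter_transition(cube, (740, 720), 1.2)
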