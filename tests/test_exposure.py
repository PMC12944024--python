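"""Adaptive exposure control: characterization, solving, densification."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.interpolate import CubicSpline

import colposim as cs


class TestCharacterizeEfficiency:
    def test_hand_arithmetic(self):
        curve = cs.characterize_efficiency([(700.0, 2550.0, 250.0)], dark_level=50.0)
        assert curve.dn_per_ms[0] == pytest.approx(10.0)

    def test_zero_signal_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="dark"):
            curve = cs.characterize_efficiency(
                [(700.0, 40.0, 100.0)], dark_level=50.0
            )
        assert curve.dn_per_ms[0] == 0.0

    def test_20nm_stride_over_650_1090_gives_23_knots(self):
        captures = [(650.0 + 20.0 * k, 500.0, 100.0) for k in range(23)]
        curve = cs.characterize_efficiency(captures, dark_level=6.0)
        assert curve.wavelengths_nm.size == 23
        assert curve.wavelengths_nm[-1] == 1090.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            cs.characterize_efficiency([], dark_level=0.0)

    def test_simulated_characterization_knot_count(self, lab_system):
        # lab grid spans 650-1095; 20 nm stride gives knots 650..1090
        curve = cs.measure_efficiency(lab_system, seed=0)
        assert curve.wavelengths_nm.size == 23
        assert curve.wavelengths_nm[0] == 650.0
        assert curve.wavelengths_nm[-1] == 1090.0


class TestSolveExposure:
    def test_target_over_efficiency(self):
        curve = cs.EfficiencyCurve([700.0, 720.0], [20.0, 20.0], 100.0)
        profile = cs.solve_exposure(curve, 3000.0, 1e6)
        assert np.allclose(profile.t_ms, 150.0)
        assert not profile.low_sensitivity_flags.any()

    def test_cap_applied_and_flagged(self):
        curve = cs.EfficiencyCurve([700.0, 720.0], [10.0, 20.0], 100.0)
        profile = cs.solve_exposure(curve, 3000.0, 300.0)
        assert profile.t_ms[0] == 300.0 and profile.low_sensitivity_flags[0]
        assert profile.t_ms[1] == 150.0 and not profile.low_sensitivity_flags[1]

    def test_halving_efficiency_doubles_uncapped_exposure(self):
        a = cs.solve_exposure(
            cs.EfficiencyCurve([700.0, 720.0], [20.0, 20.0], 1.0), 1000.0, 1e9
        )
        b = cs.solve_exposure(
            cs.EfficiencyCurve([700.0, 720.0], [10.0, 10.0], 1.0), 1000.0, 1e9
        )
        assert np.allclose(b.t_ms, 2.0 * a.t_ms)

    def test_zero_efficiency_gets_cap_and_flag(self):
        curve = cs.EfficiencyCurve([700.0, 720.0], [0.0, 10.0], 1.0)
        profile = cs.solve_exposure(curve, 1000.0, 500.0)
        assert profile.t_ms[0] == 500.0 and profile.low_sensitivity_flags[0]

    def test_unreachable_target_rejected(self):
        curve = cs.EfficiencyCurve([700.0, 720.0], [10.0, 10.0], 1.0)
        with pytest.raises(ValueError, match="saturation"):
            cs.solve_exposure(curve, 4095.0, 300.0, saturation_dn=4095)

    def test_flags_exactly_where_uncapped_exceeds_cap(self):
        eff = np.array([30.0, 12.0, 6.0, 3.0])
        curve = cs.EfficiencyCurve([700, 720, 740, 760], eff, 1.0)
        profile = cs.solve_exposure(curve, 3000.0, 300.0)
        assert list(profile.low_sensitivity_flags) == [False, False, True, True]


class TestDensifyProfile:
    def _knots(self, values, start=650.0, stride=20.0, t_max=1e6):
        grid = cs.make_grid(start, start + stride * (len(values) - 1), stride)
        return cs.ExposureProfile(
            grid, np.asarray(values, float), 700.0, t_max, "custom"
        )

    def test_constant_knots_stay_constant(self):
        dense_grid = cs.make_grid(650, 690, 5)
        dense = cs.densify_profile(self._knots([250.0, 250.0, 250.0]), dense_grid)
        assert np.allclose(dense.t_ms, 250.0)

    def test_passes_through_knots_exactly(self):
        knots = self._knots([100.0, 300.0, 280.0])
        dense_grid = cs.make_grid(650, 690, 5)
        dense = cs.densify_profile(knots, dense_grid)
        for w, t in zip(knots.grid.wavelengths, knots.t_ms):
            idx = int(np.argmin(np.abs(dense_grid.wavelengths - w)))
            assert dense.t_ms[idx] == pytest.approx(t)

    def test_no_overshoot_unlike_natural_cubic_spline(self):
        # {100, 300, 280} ms: a natural cubic spline overshoots 300 between
        # the second and third knot; the monotone-preserving fit must not.
        values = [100.0, 300.0, 280.0]
        knots = self._knots(values)
        dense_grid = cs.make_grid(650, 690, 1)
        dense = cs.densify_profile(knots, dense_grid)
        assert dense.t_ms.max() <= 300.0 + 1e-9
        naive = CubicSpline(knots.grid.wavelengths, values)
        assert naive(dense_grid.wavelengths).max() > 300.0

    def test_single_knot_rejected(self):
        # a single characterization sample cannot anchor an interpolation
        curve = cs.EfficiencyCurve([700.0], [10.0], 1.0)
        with pytest.raises(ValueError):
            cs.solve_exposure(curve, 100.0, 1e6)

    def test_cap_reapplied_after_interpolation(self):
        knots = self._knots([100.0, 300.0, 280.0], t_max=300.0)
        dense = cs.densify_profile(knots, cs.make_grid(650, 690, 1))
        assert np.all(dense.t_ms <= 300.0)
        assert dense.low_sensitivity_flags[
            int(np.argmax(dense.t_ms))
        ] == (dense.t_ms.max() >= 300.0 - 1e-9)

    @given(
        values=st.lists(st.floats(10.0, 1000.0), min_size=2, max_size=8),
    )
    def test_dense_profile_bounded_by_knot_range(self, values):
        knots = self._knots(values)
        dense_grid = cs.make_grid(650, 650 + 20 * (len(values) - 1), 5)
        dense = cs.densify_profile(knots, dense_grid)
        assert dense.t_ms.min() >= min(values) - 1e-9
        assert dense.t_ms.max() <= max(values) + 1e-9

    def test_extrapolation_holds_nearest_knot(self):
        knots = self._knots([100.0, 200.0, 150.0], start=660.0)
        dense = cs.densify_profile(knots, cs.make_grid(650, 710, 5))
        assert dense.t_ms[0] == pytest.approx(100.0)
        assert dense.t_ms[-1] == pytest.approx(150.0)


class TestTotalAcquisitionTime:
    def test_90_bands_at_250ms(self):
        grid = cs.make_grid(650, 1100, 5, "half_open")
        profile = cs.ExposureProfile.constant(grid, 250.0)
        assert cs.total_acquisition_time(profile) == pytest.approx(22.5)

    def test_empty_profile_is_zero(self):
        assert cs.total_acquisition_time([]) == 0.0

    def test_overhead_adds_n_times_overhead(self):
        grid = cs.make_grid(650, 1100, 5, "half_open")
        profile = cs.ExposureProfile.constant(grid, 250.0)
        base = cs.total_acquisition_time(profile)
        with_ovh = cs.total_acquisition_time(profile, per_band_overhead_ms=10.0)
        assert with_ovh - base == pytest.approx(90 * 10.0 / 1000.0)


class TestTradeoff:
    def test_noiseless_rmse_near_zero_for_all_strategies(self, lab_system):
        scene, truth, _ = cs.make_zenith_scene(
            lab_system.grid, seed=1, rows=12, cols=12
        )
        strategies = [
            cs.ExposureStrategy.constant(250.0),
            cs.ExposureStrategy.short_limit(500.0),
            cs.ExposureStrategy.long_limit(1200.0),
        ]
        points = cs.exposure_tradeoff_curve(
            lab_system, scene, truth, strategies, seed=0, noise=False, replicates=1
        )
        for p in points:
            assert p.rmse_pct < 0.2

    def test_strategy_ordering_with_noise(self, lab_system):
        scene, truth, _ = cs.make_zenith_scene(
            lab_system.grid, seed=11, rows=24, cols=24
        )
        strategies = [
            cs.ExposureStrategy.constant(250.0),
            cs.ExposureStrategy.short_limit(500.0),
            cs.ExposureStrategy.long_limit(1200.0),
        ]
        points = cs.exposure_tradeoff_curve(
            lab_system, scene, truth, strategies, seed=0
        )
        r = {p.strategy: p.rmse_pct for p in points}
        t = {p.strategy: p.time_s for p in points}
        assert r["long_limit"] < r["short_limit"] < r["constant"]
        assert t["long_limit"] > t["short_limit"] > t["constant"]

    def test_summary_arithmetic_matches_hand_computation(self):
        points = [
            ("constant", 28.0, 26.0),
            ("short_limit", 32.0, 12.0),
            ("long_limit", 50.0, 5.0),
        ]
        s = cs.tradeoff_summary(points)
        assert s["short_limit"]["relative_rmse_reduction_pct"] == pytest.approx(
            100 * 14 / 26
        )
        assert s["short_limit"]["reduction_pct_per_second"] == pytest.approx(
            100 * 14 / 26 / 4
        )
        assert s["long_limit"]["relative_rmse_reduction_pct"] == pytest.approx(
            100 * 21 / 26
        )


class TestProfileIO:
    def test_profile_roundtrip(self, tmp_path, lab_system):
        curve = cs.model_efficiency_curve(lab_system)
        profile = cs.solve_exposure(curve, 700.0, 500.0, grid=lab_system.grid)
        path = tmp_path / "profile.tsv"
        cs.write_profile(path, profile)
        back = cs.read_profile(path)
        assert np.allclose(back.t_ms, profile.t_ms)
        assert back.t_max_ms == profile.t_max_ms
        assert np.array_equal(
            back.low_sensitivity_flags, profile.low_sensitivity_flags
        )


def test_snr_more_uniform_under_adaptive_exposure(clinical_system):
    """Equalizing per-band signal reduces the spread of per-band SNR."""
    system = clinical_system
    curve = cs.model_efficiency_curve(system, stride_nm=5.0)
    adaptive = cs.solve_exposure(
        curve, 3000.0, 300.0, grid=system.grid, saturation_dn=system.sensor.max_dn
    )
    constant = cs.ExposureProfile.constant(system.grid, 150.0)
    scene = cs.make_flat_scene(system.grid, 0.95, rows=20, cols=20)
    roi = cs.RegionOfInterest(10, 10, 10)

    def per_band_snr(profile, seed):
        cube = cs.simulate_cube(scene, system, profile, seed=seed)
        stats = cs.extract_roi_spectrum(cube, roi)
        return 20 * np.log10(stats.mean.values / stats.sd.values)

    snr_adaptive = per_band_snr(adaptive, 1)
    snr_constant = per_band_snr(constant, 2)
    assert snr_adaptive.std() < snr_constant.std()
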