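"""QC metrics: spectral RMSE, DR/SNR dB forms, OECF, inter-band RMSE."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import colposim as cs


@pytest.fixture(scope="module")
def two_band_grid():
    return cs.make_grid(650, 655, 5)


class TestRmse:
    def test_identity_is_zero(self, small_grid):
        spec = cs.Spectrum(small_grid, np.linspace(0.2, 0.8, small_grid.n_bands))
        assert cs.rmse(spec, spec) == 0.0

    def test_orthogonal_two_band_vectors(self, two_band_grid):
        y = cs.Spectrum(two_band_grid, [1.0, 0.0])
        yhat = cs.Spectrum(two_band_grid, [0.0, 1.0])
        assert cs.rmse(y, yhat) == pytest.approx(100.0)

    def test_uniform_offset(self, small_grid):
        y = cs.Spectrum(small_grid, np.full(small_grid.n_bands, 0.5))
        yhat = cs.Spectrum(small_grid, np.full(small_grid.n_bands, 0.4))
        assert cs.rmse(y, yhat) == pytest.approx(10.0)

    def test_symmetric_in_arguments(self, small_grid):
        rng = np.random.default_rng(0)
        a = cs.Spectrum(small_grid, rng.uniform(0, 1, small_grid.n_bands))
        b = cs.Spectrum(small_grid, rng.uniform(0, 1, small_grid.n_bands))
        assert cs.rmse(a, b) == pytest.approx(cs.rmse(b, a))

    def test_scales_linearly_with_uniform_offset(self, small_grid):
        base = cs.Spectrum(small_grid, np.full(small_grid.n_bands, 0.5))
        for k in (1.0, 2.0, 3.0):
            shifted = cs.Spectrum(
                small_grid, np.full(small_grid.n_bands, 0.5 - 0.05 * k)
            )
            assert cs.rmse(base, shifted) == pytest.approx(5.0 * k)

    def test_grid_mismatch_requires_resample_flag(self, small_grid):
        coarse = cs.make_grid(650, 690, 20)
        ref = cs.Spectrum(coarse, np.full(coarse.n_bands, 0.5))
        meas = cs.Spectrum(small_grid, np.full(small_grid.n_bands, 0.5))
        with pytest.raises(ValueError, match="grid"):
            cs.rmse(ref, meas)
        assert cs.rmse(ref, meas, resample=True) == pytest.approx(0.0)


class TestDbMetrics:
    @pytest.mark.parametrize("ratio,db", [(1.0, 0.0), (10.0, 20.0), (100.0, 40.0)])
    def test_dynamic_range_closed_forms(self, ratio, db):
        result = cs.dynamic_range([ratio * 50.0] * 3, [50.0] * 3)
        assert np.allclose(result.per_band_db, db)
        assert result.global_db == pytest.approx(db)

    def test_snr_closed_forms(self):
        result = cs.snr([1000.0], [10.0])
        assert result.global_db == pytest.approx(40.0)
        assert cs.snr([5.0], [5.0]).global_db == pytest.approx(0.0)

    def test_doubling_signal_adds_6db(self):
        base = cs.snr([800.0], [10.0]).global_db
        doubled = cs.snr([1600.0], [10.0]).global_db
        assert doubled - base == pytest.approx(20 * np.log10(2), abs=1e-9)

    @given(ratio=st.floats(1e-3, 1e6))
    def test_db_matches_20log10_for_all_positive_ratios(self, ratio):
        assert cs.dynamic_range([ratio], [1.0]).global_db == pytest.approx(
            20 * np.log10(ratio), rel=1e-9
        )

    def test_zero_denominator_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="excluded"):
            result = cs.snr([100.0, 100.0], [10.0, 0.0])
        assert result.excluded[1]
        assert result.global_db == pytest.approx(20.0)

    def test_global_is_unweighted_mean_of_per_band(self):
        result = cs.dynamic_range([100.0, 1000.0], [10.0, 10.0])
        assert result.global_db == pytest.approx(result.per_band_db.mean())


class TestOecf:
    def test_density_closed_forms(self):
        nominal = cs.GRAYSCALE_REFLECTANCES
        result = cs.oecf(nominal, nominal.copy())
        assert result.densities[0] == pytest.approx(0.0223, abs=1e-4)
        assert result.densities[-1] == pytest.approx(0.6198, abs=1e-4)
        assert result.densities.size == 12

    def test_ideal_measurement_has_zero_deviation(self):
        nominal = cs.GRAYSCALE_REFLECTANCES
        result = cs.oecf(nominal, nominal.copy())
        assert result.deviation == pytest.approx(0.0, abs=1e-12)

    def test_line_residual_matches_bruteforce_scan(self):
        rng = np.random.default_rng(3)
        nominal = cs.GRAYSCALE_REFLECTANCES
        measured = nominal + rng.normal(0, 0.01, nominal.size)
        result = cs.oecf(nominal, measured)
        coef = np.polyfit(result.densities, measured, 1)
        brute = max(
            abs(m - (coef[0] * d + coef[1]))
            for d, m in zip(result.densities, measured)
        )
        assert result.line_max_residual == pytest.approx(brute)

    def test_fewer_than_three_tiles_rejected(self):
        with pytest.raises(ValueError, match="3"):
            cs.oecf([0.9, 0.5], [0.9, 0.5])

    def test_per_band_input(self):
        nominal = cs.GRAYSCALE_REFLECTANCES
        measured = np.tile(nominal[:, None], (1, 4))
        result = cs.oecf(nominal, measured)
        assert result.deviation_per_band.shape == (4,)
        assert np.allclose(result.deviation_per_band, 0.0)


class TestInterbandRmse:
    def test_identical_bands_give_zero(self, small_grid):
        data = np.full((5, 5, small_grid.n_bands), 0.5)
        cube = cs.ReflectanceCube(data, small_grid, np.zeros_like(data, bool))
        result = cs.interband_rmse(cube)
        assert np.allclose(result.per_band_pct, 0.0)
        assert result.mean_pct == 0.0

    def test_constant_step_between_bands(self, two_band_grid):
        data = np.empty((4, 4, 2))
        data[:, :, 0] = 0.50
        data[:, :, 1] = 0.55
        cube = cs.ReflectanceCube(data, two_band_grid, np.zeros_like(data, bool))
        result = cs.interband_rmse(cube)
        assert result.per_band_pct[0] == pytest.approx(5.0)
        assert result.mean_pct == pytest.approx(5.0)

    def test_single_band_rejected(self):
        grid = cs.make_grid(650, 655, 5, "half_open")  # 1 band
        data = np.full((3, 3, 1), 0.5)
        cube = cs.ReflectanceCube(data, grid, np.zeros_like(data, bool))
        with pytest.raises(ValueError, match="2 bands"):
            cs.interband_rmse(cube)


class TestCompareSystems:
    def _report(self, name="sys_a"):
        grid = cs.make_grid(460, 1000, 5)
        rng = np.random.default_rng(0)
        per_band = rng.uniform(30, 45, grid.n_bands)
        series = cs.DBSeries(per_band, float(per_band.mean()),
                             np.zeros(grid.n_bands, bool))
        return cs.CharacterizationReport(
            system_name=name,
            spatial_resolution=(100, 120),
            spectral_range_nm=(460, 1000),
            n_bands=grid.n_bands,
            avg_fwhm_nm=16.5,
            dr=series,
            snr=series,
            wavelengths_nm=grid.wavelengths,
        )

    def test_band_count_column_matches_grid(self):
        table = cs.compare_systems([self._report("a"), self._report("b")])
        assert table.loc["Number of bands", "a"] == 109

    def test_self_comparison_identical_columns(self):
        table = cs.compare_systems([self._report("a"), self._report("a2")])
        assert list(table["a"].values) == list(table["a2"].values)

    def test_max_snr_band_is_argmax_of_series(self):
        rep = self._report()
        table = cs.compare_systems([rep, self._report("b")])
        idx = int(np.argmax(rep.snr.per_band_db))
        assert table.loc["Max SNR band (nm)", "sys_a"] == rep.wavelengths_nm[idx]
        assert table.loc["Maximum SNR (dB)", "sys_a"] == pytest.approx(
            rep.snr.per_band_db.max()
        )

    def test_fewer_than_two_reports_rejected(self):
        with pytest.raises(ValueError):
            cs.compare_systems([self._report()])
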