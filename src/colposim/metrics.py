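"""QC metric suite: spectral RMSE, dynamic range, SNR, OECF linearity,
inter-band RMSE, and system comparison tables.

Conventions:

* RMSE between reference and measured reflectance is computed on fractions
  and reported x100 on the percent reflectance scale.
* Dynamic range and SNR are ``20 log10`` ratios in dB, computed per band and
  then averaged (unweighted) into a global value.
* The opto-electronic conversion function (OECF) plots measured reflectance
  against the status T density ``D = -log10(nominal reflectance)`` of a
  calibrated grayscale; an ideal system lies exactly on the reference curve
  ``R = 10**-D``, so the primary deviation statistic is the maximum absolute
  residual from that ideal curve.  Linearity statistics (least-squares line
  residual and R^2) are reported alongside.
* The signal patch for DR/SNR is the 95% grayscale tile; the dark role is
  played by the darkest available tile (nominally 24%), which is flagged in
  the report since step charts differ in their darkest step.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .calibrate import ReflectanceCube
from .grids import HSCube, Spectrum

__all__ = [
    "rmse",
    "DBSeries",
    "dynamic_range",
    "snr",
    "OECFResult",
    "oecf",
    "InterbandResult",
    "interband_rmse",
    "CharacterizationReport",
    "compare_systems",
]


def rmse(reference: Spectrum, measured: Spectrum, resample: bool = False) -> float:
    """Root-mean-square error between two reflectance spectra, in percent.

    ``sqrt(sum_i (y_i - yhat_i)^2 / N) * 100`` with ``y`` the reference and
    ``yhat`` the measured reflectance.  If the grids differ, the reference is
    linearly resampled onto the measurement grid when ``resample=True``;
    otherwise a mismatch is an error.
    """
    if not reference.grid.matches(measured.grid):
        if not resample:
            raise ValueError("spectra are on different grids (set resample=True)")
        reference = reference.resampled_to(measured.grid)
    diff = reference.values - measured.values
    return float(np.sqrt(np.mean(diff ** 2)) * 100.0)


@dataclass
class DBSeries:
    """Per-band dB values with the unweighted global mean over valid bands."""

    per_band_db: np.ndarray
    global_db: float
    excluded: np.ndarray  # bands dropped for non-positive denominators

    @property
    def max_db(self) -> float:
        valid = self.per_band_db[~self.excluded]
        return float(valid.max())

    @property
    def argmax_band(self) -> int:
        vals = np.where(self.excluded, -np.inf, self.per_band_db)
        return int(np.argmax(vals))


def _db_ratio(numer, denom, what: str) -> DBSeries:
    numer = np.atleast_1d(np.asarray(numer, dtype=float))
    denom = np.atleast_1d(np.asarray(denom, dtype=float))
    if numer.shape != denom.shape:
        raise ValueError("per-band arrays differ in length")
    excluded = denom <= 0
    if excluded.any():
        warnings.warn(
            f"{what}: {int(excluded.sum())} band(s) with non-positive "
            "denominator excluded from the global mean",
            stacklevel=3,
        )
    safe = np.where(excluded, 1.0, denom)
    per_band = 20.0 * np.log10(np.where(excluded, np.nan, numer / safe))
    global_db = float(np.nanmean(np.where(excluded, np.nan, per_band)))
    return DBSeries(per_band, global_db, excluded)


def _values(x) -> np.ndarray:
    return x.values if isinstance(x, Spectrum) else np.asarray(x, dtype=float)


def dynamic_range(white_patch_mean, dark_patch_mean) -> DBSeries:
    """DR = 20 log10( mean(W_r) / mean(D_r) ) per band, plus the global mean.

    ``W_r`` is the mean DN of the brightest (95%) grayscale tile, ``D_r`` the
    mean DN of the darkest tile.
    """
    return _db_ratio(_values(white_patch_mean), _values(dark_patch_mean), "DR")


def snr(signal_mean, noise_sd) -> DBSeries:
    """SNR = 20 log10( mean signal / noise SD ) per band, plus global mean.

    The signal is the mean DN of the bright tile; the noise is the DN
    standard deviation measured in the dark-current proxy patch.
    """
    return _db_ratio(_values(signal_mean), _values(noise_sd), "SNR")


@dataclass
class OECFResult:
    """OECF point set and deviation statistics (per band when 2-D input)."""

    densities: np.ndarray          # status T density per tile
    measured: np.ndarray           # (n_tiles,) or (n_tiles, n_bands)
    deviation: float               # max |measured - 10**-D| over everything
    deviation_per_band: np.ndarray
    line_max_residual: float       # max |residual| from per-band LS lines
    line_max_residual_per_band: np.ndarray
    r2_per_band: np.ndarray

    @property
    def ideal(self) -> np.ndarray:
        return 10.0 ** -self.densities


def oecf(nominal_reflectances, measured) -> OECFResult:
    """Opto-electronic conversion function from a grayscale step chart.

    ``nominal_reflectances`` are the tile reflectances (e.g. 0.95 .. 0.24);
    ``measured`` is the mean measured reflectance per tile, optionally per
    band (shape ``(n_tiles, n_bands)``).  Needs at least 3 tiles.
    """
    nominal = np.asarray(nominal_reflectances, dtype=float)
    meas = np.asarray(measured, dtype=float)
    if nominal.ndim != 1 or nominal.size < 3:
        raise ValueError("OECF needs at least 3 grayscale tiles")
    if np.any(nominal <= 0):
        raise ValueError("nominal reflectances must be > 0")
    if meas.shape[0] != nominal.size:
        raise ValueError("measured tiles do not match nominal tiles")
    if meas.ndim == 1:
        meas = meas[:, None]
    densities = -np.log10(nominal)
    ideal = 10.0 ** -densities

    dev_pb = np.abs(meas - ideal[:, None]).max(axis=0)
    n_bands = meas.shape[1]
    line_resid = np.empty(n_bands)
    r2 = np.empty(n_bands)
    x = densities
    for b in range(n_bands):
        y = meas[:, b]
        coef = np.polyfit(x, y, 1)
        fit = np.polyval(coef, x)
        resid = y - fit
        line_resid[b] = np.abs(resid).max()
        ss_tot = np.sum((y - y.mean()) ** 2)
        r2[b] = 1.0 - np.sum(resid ** 2) / ss_tot if ss_tot > 0 else 1.0
    return OECFResult(
        densities=densities,
        measured=meas,
        deviation=float(dev_pb.max()),
        deviation_per_band=dev_pb,
        line_max_residual=float(line_resid.max()),
        line_max_residual_per_band=line_resid,
        r2_per_band=r2,
    )


@dataclass
class InterbandResult:
    """RMSE between each band and its immediate predecessor."""

    per_band_pct: np.ndarray  # length n_bands - 1, entry i is band i+1 vs i
    mean_pct: float


def interband_rmse(cube: Union[ReflectanceCube, HSCube]) -> InterbandResult:
    """Inter-band RMSE: error between each band and the preceding band,
    over all pixels, on the percent reflectance scale.

    Elevated values indicate band-to-band misalignment from scene motion
    during a scan.  Defaults to calibrated reflectance input; a raw DN cube
    is accepted and scored on DN as a fraction of full scale.
    """
    if isinstance(cube, ReflectanceCube):
        data = cube.data
    else:
        data = cube.data.astype(float) / cube.max_dn
    if data.shape[2] < 2:
        raise ValueError("inter-band RMSE needs at least 2 bands")
    diff = np.diff(data, axis=2)
    per_band = np.sqrt((diff ** 2).mean(axis=(0, 1))) * 100.0
    return InterbandResult(per_band, float(per_band.mean()))


@dataclass
class CharacterizationReport:
    """Bundle of QC metrics for one system, plus descriptive specs."""

    system_name: str
    spatial_resolution: tuple
    spectral_range_nm: tuple
    n_bands: int
    avg_fwhm_nm: float
    rmse_pct: Optional[float] = None
    dr: Optional[DBSeries] = None
    snr: Optional[DBSeries] = None
    oecf: Optional[OECFResult] = None
    interband: Optional[InterbandResult] = None
    total_time_s: Optional[float] = None
    wavelengths_nm: Optional[np.ndarray] = None
    notes: List[str] = field(default_factory=list)

    def _max_with_band(self, series: Optional[DBSeries]):
        if series is None:
            return None, None
        idx = series.argmax_band
        lam = (
            float(self.wavelengths_nm[idx])
            if self.wavelengths_nm is not None
            else None
        )
        return series.max_db, lam

    def to_dict(self) -> dict:
        dr_max, dr_lam = self._max_with_band(self.dr)
        snr_max, snr_lam = self._max_with_band(self.snr)
        return {
            "system": self.system_name,
            "spatial_resolution": list(self.spatial_resolution),
            "spectral_range_nm": list(self.spectral_range_nm),
            "n_bands": self.n_bands,
            "avg_fwhm_nm": self.avg_fwhm_nm,
            "rmse_pct": self.rmse_pct,
            "dr_global_db": None if self.dr is None else self.dr.global_db,
            "dr_max_db": dr_max,
            "dr_max_band_nm": dr_lam,
            "snr_global_db": None if self.snr is None else self.snr.global_db,
            "snr_max_db": snr_max,
            "snr_max_band_nm": snr_lam,
            "oecf_deviation": None if self.oecf is None else self.oecf.deviation,
            "oecf_line_max_residual": (
                None if self.oecf is None else self.oecf.line_max_residual
            ),
            "interband_mean_pct": (
                None if self.interband is None else self.interband.mean_pct
            ),
            "total_time_s": self.total_time_s,
            "notes": self.notes,
        }


def compare_systems(reports: Sequence[CharacterizationReport]) -> pd.DataFrame:
    """Side-by-side specification/metric table for two or more systems."""
    if len(reports) < 2:
        raise ValueError("comparison needs at least 2 reports")
    cols = {}
    for rep in reports:
        dr_max, dr_lam = rep._max_with_band(rep.dr)
        snr_max, snr_lam = rep._max_with_band(rep.snr)
        cols[rep.system_name] = {
            "Spatial resolution (px)": f"{rep.spatial_resolution[0]} x "
            f"{rep.spatial_resolution[1]}",
            "Spectral range (nm)": f"{rep.spectral_range_nm[0]:g}-"
            f"{rep.spectral_range_nm[1]:g}",
            "Number of bands": rep.n_bands,
            "Average FWHM (nm)": rep.avg_fwhm_nm,
            "Maximum DR (dB)": dr_max,
            "Max DR band (nm)": dr_lam,
            "Maximum SNR (dB)": snr_max,
            "Max SNR band (nm)": snr_lam,
        }
    return pd.DataFrame(cols)
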