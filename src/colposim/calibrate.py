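"""White/dark reflectance calibration and min-max normalization.

The standard flat-field conversion from raw DN to reflectance is

    R = (raw - dark) / (white - dark)   per band, per pixel,

where ``white`` and ``dark`` are captures of a high-reflectance standard and
of the blocked sensor at the same exposures.  Voxels where the denominator
is within ``eps_dn`` of zero, or where raw/white is saturated, are masked
invalid rather than silently clipped.  Values slightly above 1 caused by
noise are retained (not clipped) so downstream error statistics stay
unbiased; they are exposed via ``overshoot_mask``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np

from .grids import HSCube, RegionOfInterest, SpectralGrid, Spectrum

__all__ = ["ReflectanceCube", "calibrate_reflectance", "minmax_normalize"]


@dataclass
class ReflectanceCube:
    """Calibrated reflectance fractions with an invalid-voxel mask."""

    data: np.ndarray
    grid: SpectralGrid
    invalid_mask: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.invalid_mask = np.asarray(self.invalid_mask, dtype=bool)
        if self.data.shape != self.invalid_mask.shape:
            raise ValueError("data and invalid_mask shapes differ")
        if self.data.shape[2] != self.grid.n_bands:
            raise ValueError("band count does not match grid")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("reflectance values must be finite")

    @property
    def rows(self) -> int:
        return self.data.shape[0]

    @property
    def cols(self) -> int:
        return self.data.shape[1]

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    @property
    def overshoot_mask(self) -> np.ndarray:
        """Valid voxels whose noisy reflectance exceeds 1."""
        return (self.data > 1.0) & ~self.invalid_mask

    def roi_mean(self, roi: RegionOfInterest) -> Spectrum:
        """Per-band mean reflectance over the ROI (invalid voxels excluded)."""
        roi.validate_within(self.rows, self.cols)
        block = self.data[roi.row_slice, roi.col_slice, :]
        bad = self.invalid_mask[roi.row_slice, roi.col_slice, :]
        vals = np.where(bad, np.nan, block)
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(vals.reshape(-1, self.n_bands), axis=0)
        return Spectrum(self.grid, np.nan_to_num(mean), "reflectance")


def _per_band_arrays(ref: Union[HSCube, Spectrum], like: HSCube, name: str):
    """White/dark reference as (rows, cols, bands) floats + saturation mask."""
    if isinstance(ref, Spectrum):
        if not ref.grid.matches(like.grid):
            raise ValueError(f"{name} reference grid mismatch")
        arr = np.broadcast_to(ref.values, like.data.shape)
        sat = np.zeros(like.data.shape, dtype=bool)
        return arr, sat
    if not ref.grid.matches(like.grid):
        raise ValueError(f"{name} reference grid mismatch")
    if ref.data.shape != like.data.shape:
        raise ValueError(f"{name} reference geometry mismatch")
    return ref.data.astype(float), ref.saturated_mask


def calibrate_reflectance(
    raw: HSCube,
    white: Union[HSCube, Spectrum],
    dark: Union[HSCube, Spectrum],
    eps_dn: float = 1.0,
    white_reflectance: float = 1.0,
) -> ReflectanceCube:
    """Flat-field calibration ``R_w * (raw - dark)/(white - dark)``.

    ``white``/``dark`` may be full cubes of the same geometry or per-band
    ROI-mean spectra (broadcast spatially).  ``white_reflectance`` is the
    known reflectance ``R_w`` of the white standard (diffuse panels are
    typically 0.95-0.99, not 1), so the output is absolute reflectance
    rather than reflectance relative to the panel.  Division-unstable voxels
    (``white - dark <= eps_dn``) and saturated raw/white voxels are masked
    invalid and set to 0 so the array stays finite.
    """
    if not 0 < white_reflectance <= 1:
        raise ValueError("white_reflectance must be in (0, 1]")
    w, w_sat = _per_band_arrays(white, raw, "white")
    d, _ = _per_band_arrays(dark, raw, "dark")
    num = raw.data.astype(float) - d
    den = w - d
    invalid = (den <= eps_dn) | raw.saturated_mask | w_sat
    safe_den = np.where(den <= eps_dn, 1.0, den)
    refl = np.where(invalid, 0.0, white_reflectance * num / safe_den)
    return ReflectanceCube(
        data=refl,
        grid=raw.grid,
        invalid_mask=invalid,
        metadata={"eps_dn": eps_dn, **raw.metadata},
    )


def minmax_normalize(spectrum: Spectrum) -> Spectrum:
    """Rescale to [0, 1]: ``(x - min)/(max - min)``.

    Invariant under positive affine transforms of the input; undefined (and
    an error) for a constant spectrum.
    """
    v = spectrum.values
    lo, hi = v.min(), v.max()
    if hi - lo <= 0:
        raise ValueError("min-max normalization is undefined for a constant spectrum")
    return Spectrum(spectrum.grid, (v - lo) / (hi - lo), "reflectance")
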