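"""Wavelength grids, spectra, raw cubes and region-of-interest statistics.

A hyperspectral cube produced by a tunable-filter scanner is band-sequential:
one full frame per tuned wavelength.  The wavelength axis is a uniform grid;
two endpoint conventions are in use for the same nominal range, so both are
first-class here:

* ``closed``   -- both endpoints included, ``n = span/step + 1``
  (460-1000 nm at 5 nm -> 109 bands),
* ``half_open``-- ``[start, end)``, ``n = span/step``
  (650-1100 nm at 5 nm -> 90 bands).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

__all__ = [
    "SpectralGrid",
    "make_grid",
    "grid_from_wavelengths",
    "Spectrum",
    "HSCube",
    "RegionOfInterest",
    "ROIStats",
    "extract_roi_spectrum",
]


@dataclass(frozen=True)
class SpectralGrid:
    """Uniformly spaced wavelength axis with an explicit endpoint convention."""

    start_nm: float
    end_nm: float
    step_nm: float
    convention: str = "closed"

    def __post_init__(self) -> None:
        if self.step_nm <= 0:
            raise ValueError(f"step_nm must be > 0, got {self.step_nm}")
        if not self.start_nm < self.end_nm:
            raise ValueError(
                f"start_nm must be < end_nm, got {self.start_nm} >= {self.end_nm}"
            )
        if self.convention not in ("closed", "half_open"):
            raise ValueError(f"unknown grid convention {self.convention!r}")
        span = self.end_nm - self.start_nm
        k = span / self.step_nm
        if abs(k - round(k)) > 1e-9 * max(1.0, abs(k)):
            raise ValueError(
                f"span {span:g} nm is not divisible by step {self.step_nm:g} nm "
                f"(remainder {span % self.step_nm:g} nm)"
            )

    @property
    def n_bands(self) -> int:
        k = round((self.end_nm - self.start_nm) / self.step_nm)
        return k + 1 if self.convention == "closed" else k

    @property
    def wavelengths(self) -> np.ndarray:
        return self.start_nm + self.step_nm * np.arange(self.n_bands, dtype=float)

    def matches(self, other: "SpectralGrid", tol: float = 1e-6) -> bool:
        """Same band centers (conventions may differ in naming)."""
        a, b = self.wavelengths, other.wavelengths
        return a.shape == b.shape and bool(np.allclose(a, b, atol=tol))

    def mask_between(self, lo_nm: float, hi_nm: float) -> np.ndarray:
        """Boolean mask of band centers within [lo_nm, hi_nm]."""
        w = self.wavelengths
        return (w >= lo_nm) & (w <= hi_nm)

    def to_dict(self) -> dict:
        return {
            "start_nm": self.start_nm,
            "end_nm": self.end_nm,
            "step_nm": self.step_nm,
            "convention": self.convention,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SpectralGrid":
        return cls(d["start_nm"], d["end_nm"], d["step_nm"], d["convention"])


def make_grid(
    start_nm: float, end_nm: float, step_nm: float, convention: str = "closed"
) -> SpectralGrid:
    """Build a :class:`SpectralGrid`, validating span divisibility."""
    return SpectralGrid(float(start_nm), float(end_nm), float(step_nm), convention)


def grid_from_wavelengths(wavelengths) -> SpectralGrid:
    """Recover a grid from an explicit, uniformly spaced wavelength list."""
    w = np.asarray(wavelengths, dtype=float)
    if w.ndim != 1 or w.size < 2:
        raise ValueError("need at least two wavelengths")
    steps = np.diff(w)
    if not np.allclose(steps, steps[0], atol=1e-6):
        raise ValueError("wavelengths are not uniformly spaced")
    return SpectralGrid(float(w[0]), float(w[-1]), float(steps[0]), "closed")


@dataclass
class Spectrum:
    """Per-band scalar values on a grid with an explicit unit tag.

    Units in use: ``reflectance`` (fraction), ``dn``, ``dn_per_ms``, ``ms``,
    ``db``.  Calibrated reflectance may slightly exceed 1 from noise; such
    values are retained (see :mod:`colposim.calibrate`).
    """

    grid: SpectralGrid
    values: np.ndarray
    unit: str = "reflectance"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_bands,):
            raise ValueError(
                f"values length {self.values.shape} does not match grid "
                f"band count {self.grid.n_bands}"
            )

    @property
    def wavelengths(self) -> np.ndarray:
        return self.grid.wavelengths

    def resampled_to(self, grid: SpectralGrid) -> "Spectrum":
        """Linear interpolation onto another grid (ends held)."""
        vals = np.interp(grid.wavelengths, self.wavelengths, self.values)
        return Spectrum(grid, vals, self.unit)


@dataclass
class HSCube:
    """Raw digital-number cube, (rows, cols, bands), band-sequential storage.

    ``saturated_mask`` is derived: a voxel is saturated iff its DN equals the
    full-scale value ``2**bit_depth - 1``.
    """

    data: np.ndarray
    grid: SpectralGrid
    bit_depth: int
    exposure_ms: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("cube data must be an integer DN array")
        if self.data.ndim != 3 or self.data.shape[2] != self.grid.n_bands:
            raise ValueError(
                f"data shape {self.data.shape} does not match grid band "
                f"count {self.grid.n_bands}"
            )
        if not 1 <= self.bit_depth <= 16:
            raise ValueError(f"unsupported bit depth {self.bit_depth}")
        self.exposure_ms = np.asarray(self.exposure_ms, dtype=float)
        if self.exposure_ms.shape != (self.grid.n_bands,):
            raise ValueError("exposure_ms must have one entry per band")
        if self.data.min() < 0 or self.data.max() > self.max_dn:
            raise ValueError(f"DN outside [0, {self.max_dn}]")

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
    def max_dn(self) -> int:
        return 2 ** self.bit_depth - 1

    @property
    def saturated_mask(self) -> np.ndarray:
        return self.data == self.max_dn


@dataclass(frozen=True)
class RegionOfInterest:
    """Square ROI given by center pixel and side length."""

    center_row: int
    center_col: int
    size: int

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("ROI size must be >= 1")

    @property
    def row_slice(self) -> slice:
        r0 = self.center_row - self.size // 2
        return slice(r0, r0 + self.size)

    @property
    def col_slice(self) -> slice:
        c0 = self.center_col - self.size // 2
        return slice(c0, c0 + self.size)

    def validate_within(self, rows: int, cols: int) -> None:
        rs, cs = self.row_slice, self.col_slice
        if rs.start < 0 or cs.start < 0 or rs.stop > rows or cs.stop > cols:
            raise ValueError(
                f"ROI {self} extends outside a {rows}x{cols} image"
            )


class ROIStats(NamedTuple):
    mean: Spectrum
    sd: Spectrum
    n_saturated: int


def extract_roi_spectrum(cube: HSCube, roi: RegionOfInterest) -> ROIStats:
    """Per-band mean and population SD (ddof=0) over the ROI pixels.

    Saturated voxels inside the ROI are counted and reported; they are not
    excluded from the statistics (full-scale DN is still a measurement).
    """
    roi.validate_within(cube.rows, cube.cols)
    block = cube.data[roi.row_slice, roi.col_slice, :].astype(float)
    mean = Spectrum(cube.grid, block.mean(axis=(0, 1)), "dn")
    sd = Spectrum(cube.grid, block.std(axis=(0, 1), ddof=0), "dn")
    n_sat = int(cube.saturated_mask[roi.row_slice, roi.col_slice, :].sum())
    return ROIStats(mean, sd, n_sat)
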