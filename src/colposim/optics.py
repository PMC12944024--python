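"""Radiometric forward model of the tunable-filter acquisition chain.

The expected detector signal for a band tuned to center wavelength ``c`` is

    DN(R, c, t) = clip( dark_offset + dark_rate * t
                        + gain * flux_scale * throughput * t
                          * R * integral E(lam) T(lam; c) QE(lam) dlam,
                        0, 2**bit_depth - 1 )

with ``E`` the illuminant relative spectral power, ``T`` the tunable passband
transmission, ``QE`` the sensor quantum efficiency, ``R`` the scene
reflectance at the band and ``t`` the exposure in ms.  Absolute radiometry is
abstracted: ``flux_scale`` folds the photon-flux scale into photoelectrons
per (unit band integral) per millisecond, so the model is calibrated in DN
and ratios only.  Below saturation the signal is exactly affine in both
exposure and reflectance.

Presets mirror three instrument configurations: a laboratory NIR setup with
the tunable filter in the emission path (EFS) or the reception path (RFS,
12.5% of the EFS throughput), a clinical dual-filter system covering
460-1000 nm with a 12-bit sensor, and a snapshot-mosaic-style comparison
system with strongly wavelength-dependent sensitivity.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator

from .grids import SpectralGrid, make_grid

__all__ = [
    "IlluminantModel",
    "PassbandModel",
    "SensorModel",
    "Channel",
    "OpticalSystemModel",
    "expected_dn",
    "matched_exposure",
    "emission_filtering_lab",
    "reception_filtering_lab",
    "clinical_dual_lctf",
    "snapscan_like",
    "SYSTEM_PRESETS",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class IlluminantModel:
    """Relative spectral power E(lambda) >= 0 on a finite support."""

    kind: str
    power_fn: Callable[[np.ndarray], np.ndarray]
    support_nm: tuple

    def power(self, lam) -> np.ndarray:
        lam = np.asarray(lam, dtype=float)
        lo, hi = self.support_nm
        out = np.where((lam >= lo) & (lam <= hi), self.power_fn(lam), 0.0)
        return np.clip(out, 0.0, None)

    @classmethod
    def halogen_broadband(
        cls, temp_k: float = 3200.0, support_nm: tuple = (400.0, 1750.0)
    ) -> "IlluminantModel":
        """Incandescent source: relative Planck spectrum, max-normalized."""
        c2 = 1.4388e7  # nm*K

        def planck(lam):
            lam = np.asarray(lam, dtype=float)
            return lam ** -5.0 / np.expm1(c2 / (lam * temp_k))

        ref = np.linspace(*support_nm, 2048)
        peak = planck(ref).max()
        return cls("halogen_broadband", lambda lam: planck(lam) / peak, support_nm)

    @classmethod
    def led_highcri(
        cls,
        flat_nm: tuple = (425.0, 700.0),
        rise_nm: float = 10.0,
        tail_nm: float = 40.0,
    ) -> "IlluminantModel":
        """High-CRI white LED: near-uniform over 420-700 nm with soft edges."""
        lo, hi = flat_nm

        def power(lam):
            lam = np.asarray(lam, dtype=float)
            up = np.clip((lam - (lo - rise_nm)) / rise_nm, 0.0, 1.0)
            down = np.clip((hi + tail_nm - lam) / tail_nm, 0.0, 1.0)
            return 0.5 * (1 - np.cos(np.pi * up)) * 0.5 * (1 - np.cos(np.pi * down))

        return cls("led_highcri", power, (lo - rise_nm, hi + tail_nm))

    @classmethod
    def flat(cls, lo_nm: float, hi_nm: float, level: float = 1.0) -> "IlluminantModel":
        return cls(
            "custom", lambda lam: np.full_like(np.asarray(lam, float), level),
            (lo_nm, hi_nm),
        )

    @classmethod
    def custom(cls, power_fn, support_nm) -> "IlluminantModel":
        return cls("custom", power_fn, tuple(support_nm))


@dataclass
class PassbandModel:
    """Tunable narrow passband with wavelength-dependent FWHM.

    The FWHM ramps linearly between ``fwhm_nm[0]`` at ``range_nm[0]`` and
    ``fwhm_nm[1]`` at ``range_nm[1]`` (default 9 -> 24 nm).  ``shape`` is
    ``gaussian`` (default) or ``rect`` (ideal top-hat, used for closed-form
    cross-checks).  ``leakage`` is the out-of-band transmission floor.
    """

    range_nm: tuple = (650.0, 1100.0)
    fwhm_nm: tuple = (9.0, 24.0)
    peak_transmission: float = 0.45
    leakage: float = 1e-4
    shape: str = "gaussian"

    def __post_init__(self) -> None:
        if not 0 < self.peak_transmission <= 1:
            raise ValueError("peak_transmission must be in (0, 1]")
        if min(self.fwhm_nm) <= 0:
            raise ValueError("FWHM must be positive")
        if self.shape not in ("gaussian", "rect"):
            raise ValueError(f"unknown passband shape {self.shape!r}")

    def fwhm(self, center_nm: float) -> float:
        lo, hi = self.range_nm
        f0, f1 = self.fwhm_nm
        x = np.clip((center_nm - lo) / (hi - lo), 0.0, 1.0)
        return float(f0 + (f1 - f0) * x)

    @property
    def mean_fwhm(self) -> float:
        return 0.5 * (self.fwhm_nm[0] + self.fwhm_nm[1])

    def transmission(self, lam, center_nm: float) -> np.ndarray:
        lam = np.asarray(lam, dtype=float)
        f = self.fwhm(center_nm)
        core = self.peak_transmission - self.leakage
        if self.shape == "rect":
            inside = np.abs(lam - center_nm) <= f / 2.0
            return self.leakage + core * inside
        sigma = f * _FWHM_TO_SIGMA
        return self.leakage + core * np.exp(-0.5 * ((lam - center_nm) / sigma) ** 2)


@dataclass
class SensorModel:
    """Quantum-efficiency curve plus gain, noise and quantization parameters.

    ``gain_dn_per_e`` converts photoelectrons to DN; shot noise is Poisson in
    electrons, read noise Gaussian with ``read_noise_e`` electrons RMS, dark
    signal is ``dark_offset_dn + dark_rate_dn_per_ms * t``.
    """

    name: str
    qe_wavelengths_nm: Sequence[float]
    qe_values: Sequence[float]
    bit_depth: int
    gain_dn_per_e: float
    read_noise_e: float
    dark_rate_dn_per_ms: float
    dark_offset_dn: float
    _interp: Optional[PchipInterpolator] = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        w = np.asarray(self.qe_wavelengths_nm, dtype=float)
        q = np.asarray(self.qe_values, dtype=float)
        if np.any(q < 0) or np.any(q > 1):
            raise ValueError("quantum efficiency must lie in [0, 1]")
        self.qe_wavelengths_nm = w
        self.qe_values = q
        self._interp = PchipInterpolator(w, q, extrapolate=False)

    def qe(self, lam) -> np.ndarray:
        lam = np.clip(
            np.asarray(lam, dtype=float),
            self.qe_wavelengths_nm[0],
            self.qe_wavelengths_nm[-1],
        )
        return np.clip(self._interp(lam), 0.0, 1.0)

    @property
    def max_dn(self) -> int:
        return 2 ** self.bit_depth - 1

    @classmethod
    def nir_10bit(cls) -> "SensorModel":
        """NIR-enhanced CMOS: QE peaking ~60% near 600 nm, ~5% at 1000 nm."""
        return cls(
            name="nir_10bit",
            qe_wavelengths_nm=[400, 500, 600, 700, 800, 900, 1000, 1100],
            qe_values=[0.35, 0.52, 0.60, 0.50, 0.32, 0.15, 0.05, 0.02],
            bit_depth=10,
            gain_dn_per_e=0.25,
            read_noise_e=6.0,
            dark_rate_dn_per_ms=0.005,
            dark_offset_dn=6.0,
        )

    @classmethod
    def vis_nir_12bit(cls) -> "SensorModel":
        """Low-noise 12-bit CMOS: QE ~72% over 525-580 nm, low read noise."""
        return cls(
            name="vis_nir_12bit",
            qe_wavelengths_nm=[400, 460, 525, 580, 650, 750, 850, 950, 1000, 1100],
            qe_values=[0.45, 0.60, 0.72, 0.72, 0.65, 0.50, 0.33, 0.16, 0.10, 0.05],
            bit_depth=12,
            gain_dn_per_e=0.5,
            read_noise_e=2.5,
            dark_rate_dn_per_ms=0.005,
            dark_offset_dn=40.0,
        )

    @classmethod
    def snapscan_mosaic_10bit(cls) -> "SensorModel":
        """Mosaic-filter style sensor with strong band-to-band QE swings."""
        return cls(
            name="snapscan_mosaic_10bit",
            qe_wavelengths_nm=[450, 500, 550, 600, 650, 700, 750, 800, 850, 900],
            qe_values=[0.30, 0.45, 0.50, 0.20, 0.18, 0.45, 0.35, 0.25, 0.15, 0.08],
            bit_depth=10,
            gain_dn_per_e=0.25,
            read_noise_e=7.0,
            dark_rate_dn_per_ms=0.002,
            dark_offset_dn=6.0,
        )

    @classmethod
    def constant_qe(cls, qe: float, bit_depth: int = 12, **kw) -> "SensorModel":
        """Flat-QE sensor for closed-form checks."""
        params = dict(
            gain_dn_per_e=0.5,
            read_noise_e=0.0,
            dark_rate_dn_per_ms=0.0,
            dark_offset_dn=0.0,
        )
        params.update(kw)
        return cls(
            name="constant_qe",
            qe_wavelengths_nm=[300, 2000],
            qe_values=[qe, qe],
            bit_depth=bit_depth,
            **params,
        )


@dataclass
class Channel:
    """One illumination/filter path, active for band centers in [lo, hi)."""

    lo_nm: float
    hi_nm: float
    illuminant: IlluminantModel
    passband: PassbandModel


@dataclass
class OpticalSystemModel:
    """Complete acquisition chain: illuminant(s) -> passband -> sensor -> DN."""

    name: str
    grid: SpectralGrid
    channels: list
    sensor: SensorModel
    throughput: float
    flux_scale: float
    mode: str = "emission_filtering"
    filter_transition: Optional[tuple] = None  # (lo_nm, hi_nm, magnitude)
    _flux_cache: dict = field(default_factory=dict, repr=False, compare=False)
    _leak_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not 0 < self.throughput <= 1:
            raise ValueError("throughput must be in (0, 1]")
        if self.mode not in ("emission_filtering", "reception_filtering"):
            raise ValueError(f"unknown mode {self.mode!r}")

    # -- geometry of the spectral chain ------------------------------------
    def channel_for(self, center_nm: float) -> Channel:
        for i, ch in enumerate(self.channels):
            last = i == len(self.channels) - 1
            if ch.lo_nm <= center_nm < ch.hi_nm or (last and center_nm == ch.hi_nm):
                return ch
        raise ValueError(f"no channel covers {center_nm} nm in system {self.name!r}")

    def _leak_flux(self, ch: Channel) -> float:
        key = id(ch)
        if key not in self._leak_cache:
            lam = np.linspace(*ch.illuminant.support_nm, 2048)
            integrand = ch.illuminant.power(lam) * self.sensor.qe(lam)
            self._leak_cache[key] = ch.passband.leakage * float(
                np.trapezoid(integrand, lam)
            )
        return self._leak_cache[key]

    def band_flux(self, center_nm: float) -> float:
        """Quadrature of E(lam) T(lam; c) QE(lam) over the passband."""
        key = float(center_nm)
        if key in self._flux_cache:
            return self._flux_cache[key]
        ch = self.channel_for(center_nm)
        pb = ch.passband
        f = pb.fwhm(center_nm)
        core = pb.peak_transmission - pb.leakage
        if pb.shape == "rect":
            # integrand is smooth inside the exact support: no edge error
            lam = np.linspace(center_nm - f / 2, center_nm + f / 2, 257)
            weight = core
            win = ch.illuminant.power(lam) * self.sensor.qe(lam)
            val = weight * float(np.trapezoid(win, lam))
        else:
            sigma = f * _FWHM_TO_SIGMA
            lam = np.linspace(center_nm - 6 * sigma, center_nm + 6 * sigma, 481)
            gauss = np.exp(-0.5 * ((lam - center_nm) / sigma) ** 2)
            win = ch.illuminant.power(lam) * self.sensor.qe(lam) * core * gauss
            val = float(np.trapezoid(win, lam))
        val += self._leak_flux(ch)
        self._flux_cache[key] = val
        return val

    # -- radiometry ---------------------------------------------------------
    def electrons_per_ms(self, center_nm: float, reflectance: float = 1.0) -> float:
        return self.flux_scale * self.throughput * self.band_flux(center_nm) * reflectance

    def dark_dn(self, exposure_ms: float) -> float:
        s = self.sensor
        return s.dark_offset_dn + s.dark_rate_dn_per_ms * exposure_ms

    def signal_dn(self, reflectance, center_nm: float, exposure_ms) -> np.ndarray:
        """Unclipped signal above dark, in DN (affine in R and t)."""
        e = self.electrons_per_ms(center_nm)
        return (
            self.sensor.gain_dn_per_e
            * e
            * np.asarray(exposure_ms, dtype=float)
            * np.asarray(reflectance, dtype=float)
        )

    def expected_dn(self, reflectance, center_nm: float, exposure_ms) -> np.ndarray:
        dn = self.dark_dn(np.asarray(exposure_ms, dtype=float)) + self.signal_dn(
            reflectance, center_nm, exposure_ms
        )
        return np.clip(dn, 0.0, self.sensor.max_dn)

    def efficiency_dn_per_ms(
        self, center_nm: float, white_reflectance: float = 0.95
    ) -> float:
        """Model-based signal-above-dark rate against a white standard."""
        return float(
            self.sensor.gain_dn_per_e
            * self.electrons_per_ms(center_nm, white_reflectance)
        )

    def noise_var_dn(self, reflectance, center_nm: float, exposure_ms) -> np.ndarray:
        """Predicted per-pixel DN variance: shot + read + quantization."""
        g = self.sensor.gain_dn_per_e
        n_e = (
            self.electrons_per_ms(center_nm)
            * np.asarray(exposure_ms, dtype=float)
            * np.asarray(reflectance, dtype=float)
        )
        return g * g * (n_e + self.sensor.read_noise_e ** 2) + 1.0 / 12.0

    def replaced(self, **changes) -> "OpticalSystemModel":
        """Copy with fields replaced (caches reset)."""
        changes.setdefault("_flux_cache", {})
        changes.setdefault("_leak_cache", {})
        return dataclasses.replace(self, **changes)


def expected_dn(
    reflectance, system: OpticalSystemModel, band_nm: float, exposure_ms
) -> np.ndarray:
    """Expected (noise-free) DN for a band; clipped to the sensor range."""
    if np.any(np.asarray(exposure_ms) <= 0):
        raise ValueError("exposure must be > 0")
    return system.expected_dn(reflectance, band_nm, exposure_ms)


def matched_exposure(
    system_ref: OpticalSystemModel,
    system_other: OpticalSystemModel,
    band_nm: float,
    exposure_ref_ms: float,
) -> float:
    """Exposure the second system needs to match the first system's signal.

    Under the linear model the matched exposure scales with the efficiency
    ratio; an 87.5% throughput deficit therefore maps 250 ms to 2000 ms.
    """
    e_ref = system_ref.efficiency_dn_per_ms(band_nm, 1.0)
    e_other = system_other.efficiency_dn_per_ms(band_nm, 1.0)
    if e_other <= 0:
        raise ValueError("second system has zero efficiency at this band")
    return float(exposure_ref_ms * e_ref / e_other)


# ---------------------------------------------------------------------------
# Instrument presets
# ---------------------------------------------------------------------------

def emission_filtering_lab() -> OpticalSystemModel:
    """Laboratory NIR setup, tunable filter in the illumination path.

    650-1100 nm in 90 half-open 5 nm bands, 10-bit NIR-enhanced sensor,
    broadband halogen source.
    """
    grid = make_grid(650, 1100, 5, "half_open")
    ch = Channel(
        650.0,
        1100.0,
        IlluminantModel.halogen_broadband(),
        PassbandModel(range_nm=(650, 1100), fwhm_nm=(9, 24)),
    )
    return OpticalSystemModel(
        name="efs_lab",
        grid=grid,
        channels=[ch],
        sensor=SensorModel.nir_10bit(),
        throughput=0.8,
        flux_scale=6.9,
        mode="emission_filtering",
    )


def reception_filtering_lab() -> OpticalSystemModel:
    """Same optics with the filter in the reception path: 12.5% throughput."""
    efs = emission_filtering_lab()
    return efs.replaced(
        name="rfs_lab", throughput=efs.throughput * 0.125, mode="reception_filtering"
    )


def clinical_dual_lctf() -> OpticalSystemModel:
    """Clinical dual-filter system: 460-1000 nm closed grid, 109 bands.

    A visible channel (high-CRI LED + VIS filter) serves band centers below
    720 nm and an NIR channel (halogen + NIR filter) the rest; the hand-off
    between the two optical paths produces a localized artefact at
    720-740 nm, modeled as a multiplicative band-local perturbation.
    """
    grid = make_grid(460, 1000, 5, "closed")
    vis = Channel(
        460.0,
        720.0,
        IlluminantModel.led_highcri(),
        PassbandModel(range_nm=(420, 730), fwhm_nm=(9, 16)),
    )
    nir = Channel(
        720.0,
        1000.0,
        IlluminantModel.halogen_broadband(support_nm=(500.0, 1600.0)),
        PassbandModel(range_nm=(650, 1100), fwhm_nm=(9, 24)),
    )
    return OpticalSystemModel(
        name="clinical_lctf",
        grid=grid,
        channels=[vis, nir],
        sensor=SensorModel.vis_nir_12bit(),
        throughput=0.8,
        flux_scale=12.0,
        mode="emission_filtering",
        filter_transition=(720.0, 740.0, 1.15),
    )


def snapscan_like() -> OpticalSystemModel:
    """Spatio-spectral-scanning comparison system, 470-900 nm, 10-bit.

    Sensitivity swings strongly across bands (mosaic-style sensor), the
    hallmark that motivates adaptive exposure in the tunable-filter design.
    """
    grid = make_grid(470, 900, 5, "closed")
    ch = Channel(
        470.0,
        900.0,
        IlluminantModel.halogen_broadband(support_nm=(420.0, 1000.0)),
        PassbandModel(range_nm=(470, 900), fwhm_nm=(7, 7), peak_transmission=0.6),
    )
    return OpticalSystemModel(
        name="snapscan_like",
        grid=grid,
        channels=[ch],
        sensor=SensorModel.snapscan_mosaic_10bit(),
        throughput=0.5,
        flux_scale=25.0,
        mode="reception_filtering",
    )


SYSTEM_PRESETS = {
    "efs_lab": emission_filtering_lab,
    "rfs_lab": reception_filtering_lab,
    "clinical_lctf": clinical_dual_lctf,
    "snapscan_like": snapscan_like,
}
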