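"""Cube simulation: spectral scanning, spatio-spectral scanning, artefacts.

Noise model per voxel (band b, exposure t):

* shot noise: Poisson in photoelectrons, scaled by the sensor gain,
* read noise: Gaussian, ``read_noise_e`` electrons RMS,
* dark signal: deterministic ``dark_offset + dark_rate * t``,
* quantization: round to integer DN, clip to ``[0, 2**bit_depth - 1]``.

Draw order is fixed (bands in grid order; per band one Poisson draw then one
Gaussian draw over the full frame), so a given seed reproduces a cube
bit-exactly.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exposure import ExposureProfile
from .grids import HSCube
from .optics import OpticalSystemModel
from .scenes import SceneTarget

__all__ = [
    "MotionModel",
    "simulate_cube",
    "simulate_spatioscan_cube",
    "inject_filter_transition",
]


@dataclass
class MotionModel:
    """Inter-frame scene motion during a scan.

    ``amplitude_px`` is the per-frame shift scale in pixels; ``axis`` is the
    image axis shifted (1 = columns, producing vertical misalignment bands).
    ``schedule`` is ``drift`` (constant shift per frame) or ``random_walk``
    (seeded Gaussian steps of SD ``amplitude_px``).  Zero amplitude
    reproduces the static case exactly.
    """

    amplitude_px: float = 0.0
    axis: int = 1
    schedule: str = "drift"

    def __post_init__(self) -> None:
        if self.amplitude_px < 0:
            raise ValueError("amplitude must be >= 0")
        if self.schedule not in ("drift", "random_walk"):
            raise ValueError(f"unknown motion schedule {self.schedule!r}")
        if self.axis not in (0, 1):
            raise ValueError("axis must be 0 (rows) or 1 (columns)")

    def shifts(self, n_frames: int, rng: np.random.Generator) -> np.ndarray:
        """Cumulative integer shift of the scene at each frame."""
        if self.amplitude_px == 0:
            return np.zeros(n_frames, dtype=int)
        if self.schedule == "drift":
            cum = self.amplitude_px * np.arange(n_frames)
        else:
            cum = np.cumsum(rng.normal(0.0, self.amplitude_px, n_frames))
        return np.rint(cum).astype(int)


def _check_grids(scene: SceneTarget, profile: ExposureProfile) -> None:
    if not scene.grid.matches(profile.grid):
        raise ValueError("scene and exposure profile are on different grids")


def _expose(
    refl: np.ndarray,
    system: OpticalSystemModel,
    profile: ExposureProfile,
    rng,
    noise: bool,
    metadata: dict,
) -> HSCube:
    """Turn per-band reflectance maps into a quantized DN cube."""
    sensor = system.sensor
    g = sensor.gain_dn_per_e
    wavelengths = profile.grid.wavelengths
    rows, cols, n_bands = refl.shape
    data = np.empty((rows, cols, n_bands), dtype=np.uint16)
    for b in range(n_bands):
        t = profile.t_ms[b]
        n_e = system.electrons_per_ms(wavelengths[b]) * t * refl[:, :, b]
        if noise:
            counts = rng.poisson(n_e).astype(float)
            signal = g * counts + rng.normal(0.0, g * sensor.read_noise_e, n_e.shape)
        else:
            signal = g * n_e
        dn = system.dark_dn(t) + signal
        data[:, :, b] = np.clip(np.rint(dn), 0, sensor.max_dn).astype(np.uint16)
    return HSCube(
        data=data,
        grid=profile.grid,
        bit_depth=sensor.bit_depth,
        exposure_ms=profile.t_ms.copy(),
        metadata=metadata,
    )


def simulate_cube(
    scene: SceneTarget,
    system: OpticalSystemModel,
    profile: ExposureProfile,
    seed: int = 0,
    noise: bool = True,
) -> HSCube:
    """Spectral scanning: one full static frame per tuned band."""
    _check_grids(scene, profile)
    rng = np.random.default_rng(seed)
    refl = scene.reflectance_map()
    meta = {"scan": "spectral", "seed": int(seed), "system": system.name}
    return _expose(refl, system, profile, rng, noise, meta)


def simulate_spatioscan_cube(
    scene: SceneTarget,
    system: OpticalSystemModel,
    profile: ExposureProfile,
    motion: MotionModel,
    seed: int = 0,
    noise: bool = True,
) -> HSCube:
    """Spatio-spectral scanning with inter-frame scene motion.

    Each output band is assembled from diagonal spatial-spectral planes by
    nearest-frame assignment: rows in the first image half are taken from the
    frame at the band's nominal time, the second half from the next frame.
    With the scene shifting between frames this yields the characteristic
    band-to-band misalignment; with zero motion the output is bit-identical
    to :func:`simulate_cube` at the same seed.
    """
    _check_grids(scene, profile)
    rng = np.random.default_rng(seed)
    motion_rng = np.random.default_rng([int(seed), 0x5CA7])
    refl0 = scene.reflectance_map()
    n_bands = profile.grid.n_bands
    half = scene.rows // 2
    shifts = motion.shifts(n_bands + 1, motion_rng)
    refl = np.empty_like(refl0)
    for b in range(n_bands):
        top = np.roll(refl0, shifts[b], axis=motion.axis)
        if shifts[b + 1] == shifts[b]:
            refl[:, :, b] = top[:, :, b]
        else:
            bottom = np.roll(refl0, shifts[b + 1], axis=motion.axis)
            refl[:half, :, b] = top[:half, :, b]
            refl[half:, :, b] = bottom[half:, :, b]
    meta = {
        "scan": "spatio_spectral",
        "seed": int(seed),
        "system": system.name,
        "motion_amplitude_px": motion.amplitude_px,
        "motion_schedule": motion.schedule,
    }
    return _expose(refl, system, profile, rng, noise, meta)


def inject_filter_transition(
    cube: HSCube, band_range_nm: tuple = (720.0, 740.0), magnitude: float = 1.15
) -> HSCube:
    """Apply the dual-filter hand-off artefact: a multiplicative perturbation
    on the bands whose centers fall inside ``band_range_nm``.

    Affected band indices are recorded in the cube metadata.  Magnitude 1.0
    leaves the cube unchanged.
    """
    lo, hi = band_range_nm
    grid = cube.grid
    if lo >= hi:
        raise ValueError("band range must satisfy lo < hi")
    if hi < grid.wavelengths[0] or lo > grid.wavelengths[-1]:
        raise ValueError(
            f"band range {band_range_nm} lies outside the grid "
            f"({grid.wavelengths[0]:g}-{grid.wavelengths[-1]:g} nm)"
        )
    mask = grid.mask_between(lo, hi)
    data = cube.data.astype(float)
    data[:, :, mask] = np.rint(data[:, :, mask] * magnitude)
    data = np.clip(data, 0, cube.max_dn).astype(np.uint16)
    meta = dict(cube.metadata)
    meta["transition_bands"] = [int(i) for i in np.flatnonzero(mask)]
    meta["transition_magnitude"] = float(magnitude)
    return HSCube(
        data=data,
        grid=grid,
        bit_depth=cube.bit_depth,
        exposure_ms=cube.exposure_ms.copy(),
        metadata=meta,
    )
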