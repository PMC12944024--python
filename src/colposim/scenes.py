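"""Reference-target scene generators.

Scenes are reflectance maps with labeled rectangular patches:

* a flat uniform target (white/dark references, single-reflectance tests),
* a resolution/color checker: a 6 x 7 matrix of color patches around a
  central 12-step grayscale running 95% -> 24% reflectance,
* a rare-earth-doped polymer wavelength standard emulated as a smooth
  baseline with a few narrow absorption dips whose positions and depths are
  returned as ground truth (synthetic stand-in; the real manufacturer
  spectrum is not published).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .grids import RegionOfInterest, SpectralGrid, Spectrum

__all__ = [
    "Patch",
    "SceneTarget",
    "make_flat_scene",
    "make_rezchecker_scene",
    "DipSpec",
    "make_zenith_like_reference",
    "make_zenith_scene",
    "gaussian_smooth",
    "GRAYSCALE_REFLECTANCES",
]

# 12 grayscale tiles, 95% down to 24% reflectance, equally spaced.
GRAYSCALE_REFLECTANCES = np.linspace(0.95, 0.24, 12)


@dataclass
class Patch:
    label: str
    row0: int
    col0: int
    height: int
    width: int
    reflectance: Spectrum

    def overlaps(self, other: "Patch") -> bool:
        return not (
            self.row0 + self.height <= other.row0
            or other.row0 + other.height <= self.row0
            or self.col0 + self.width <= other.col0
            or other.col0 + other.width <= self.col0
        )


@dataclass
class SceneTarget:
    """Labeled patch layout over a uniform background reflectance."""

    rows: int
    cols: int
    grid: SpectralGrid
    patches: List[Patch] = field(default_factory=list)
    background: Optional[Spectrum] = None

    def __post_init__(self) -> None:
        if self.background is None:
            self.background = Spectrum(
                self.grid, np.full(self.grid.n_bands, 0.05), "reflectance"
            )
        for p in self.patches:
            if (
                p.row0 < 0
                or p.col0 < 0
                or p.row0 + p.height > self.rows
                or p.col0 + p.width > self.cols
            ):
                raise ValueError(f"patch {p.label!r} outside scene bounds")
            if not p.reflectance.grid.matches(self.grid):
                raise ValueError(f"patch {p.label!r} grid mismatch")
        for i, a in enumerate(self.patches):
            for b in self.patches[i + 1 :]:
                if a.overlaps(b):
                    raise ValueError(f"patches {a.label!r} and {b.label!r} overlap")

    def reflectance_map(self) -> np.ndarray:
        """(rows, cols, bands) reflectance fractions."""
        out = np.broadcast_to(
            self.background.values, (self.rows, self.cols, self.grid.n_bands)
        ).copy()
        for p in self.patches:
            out[p.row0 : p.row0 + p.height, p.col0 : p.col0 + p.width, :] = (
                p.reflectance.values
            )
        return out

    def patch(self, label: str) -> Patch:
        for p in self.patches:
            if p.label == label:
                return p
        raise KeyError(f"no patch labeled {label!r}")

    def roi_for(self, label: str, size: Optional[int] = None) -> RegionOfInterest:
        """Centered square ROI inside a patch (defaults to the largest fit)."""
        p = self.patch(label)
        if size is None:
            size = min(p.height, p.width)
        if size > min(p.height, p.width):
            raise ValueError(f"ROI size {size} exceeds patch {label!r}")
        return RegionOfInterest(p.row0 + p.height // 2, p.col0 + p.width // 2, size)


def make_flat_scene(
    grid: SpectralGrid,
    reflectance=0.95,
    rows: int = 32,
    cols: int = 32,
    label: str = "flat",
) -> SceneTarget:
    """Uniform target; ``reflectance`` may be a scalar or a Spectrum."""
    if isinstance(reflectance, Spectrum):
        spec = reflectance
    else:
        spec = Spectrum(grid, np.full(grid.n_bands, float(reflectance)), "reflectance")
    patch = Patch(label, 0, 0, rows, cols, spec)
    return SceneTarget(rows, cols, grid, [patch], background=spec)


def _color_patch_spectrum(grid: SpectralGrid, index: int) -> Spectrum:
    """Deterministic gently sloped spectrum for color-checker patch ``index``."""
    w = grid.wavelengths
    x = (w - w[0]) / (w[-1] - w[0])
    level = 0.12 + 0.75 * ((index * 7) % 11) / 10.0
    slope = 0.25 * (((index * 3) % 7) - 3) / 3.0
    vals = np.clip(level + slope * (x - 0.5), 0.03, 0.97)
    return Spectrum(grid, vals, "reflectance")


def make_rezchecker_scene(grid: SpectralGrid, patch_px: int = 12) -> SceneTarget:
    """Checker target: 42 color patches + central 12-tile grayscale strip.

    Color patches are flat or gently sloped spectra (deterministic by
    position); grayscale tiles carry nominal flat reflectances from 0.95
    (tile 1) down to 0.24 (tile 12).
    """
    gap = 2
    margin = 4
    gray_w = max(6, patch_px * 2 // 3)
    strip_w = 12 * gray_w + 11 * gap
    color_w = max(patch_px, (strip_w - 6 * gap) // 7)
    width = margin * 2 + max(strip_w, 7 * color_w + 6 * gap)

    patches: List[Patch] = []
    row = margin
    idx = 0
    for r in range(6):
        if r == 3:  # central grayscale strip between color rows 3 and 4
            row += gap
            for i, refl in enumerate(GRAYSCALE_REFLECTANCES):
                spec = Spectrum(
                    grid, np.full(grid.n_bands, float(refl)), "reflectance"
                )
                patches.append(
                    Patch(
                        f"gray{i + 1:02d}",
                        row,
                        margin + i * (gray_w + gap),
                        patch_px,
                        gray_w,
                        spec,
                    )
                )
            row += patch_px + gap * 2
        for c in range(7):
            patches.append(
                Patch(
                    f"color_{r}{c}",
                    row,
                    margin + c * (color_w + gap),
                    patch_px,
                    color_w,
                    _color_patch_spectrum(grid, idx),
                )
            )
            idx += 1
        row += patch_px + gap
    height = row - gap + margin
    return SceneTarget(height, width, grid, patches)


@dataclass(frozen=True)
class DipSpec:
    """Ground truth for one absorption feature of the synthetic standard."""

    center_nm: float
    depth: float
    sigma_nm: float


def make_zenith_like_reference(
    grid: SpectralGrid, seed: int = 0, n_dips: int = 4
) -> tuple:
    """Synthetic diffuse-reflectance standard with narrow absorption dips.

    Returns ``(spectrum, dips)`` where ``dips`` is the ground-truth list of
    :class:`DipSpec`.  Values stay within [0, 1].  This is an explicit
    synthetic stand-in for a rare-earth-doped polymer standard whose true
    spectrum is proprietary; only feature structure, not absolute values,
    is meaningful.
    """
    rng = np.random.default_rng(seed)
    w = grid.wavelengths
    span = w[-1] - w[0]
    x = (w - w[0]) / span
    baseline = 0.92 - 0.05 * x + 0.02 * np.sin(2 * np.pi * x)

    centers: list = []
    for _ in range(10000):
        if len(centers) == n_dips:
            break
        c = rng.uniform(w[0] + 0.06 * span, w[-1] - 0.06 * span)
        if all(abs(c - c0) > 40.0 for c0 in centers):
            centers.append(float(c))
    dips = [
        DipSpec(
            center_nm=c,
            depth=float(rng.uniform(0.15, 0.35)),
            sigma_nm=float(rng.uniform(3.0, 8.0)),
        )
        for c in sorted(centers)
    ]
    vals = baseline.copy()
    for d in dips:
        vals *= 1.0 - d.depth * np.exp(-0.5 * ((w - d.center_nm) / d.sigma_nm) ** 2)
    vals = np.clip(vals, 0.0, 1.0)
    return Spectrum(grid, vals, "reflectance"), dips


def make_zenith_scene(
    grid: SpectralGrid, seed: int = 0, rows: int = 32, cols: int = 32
) -> tuple:
    """Flat scene of the synthetic wavelength standard; returns (scene, truth, dips)."""
    spectrum, dips = make_zenith_like_reference(grid, seed=seed)
    scene = make_flat_scene(grid, spectrum, rows=rows, cols=cols, label="zenith")
    return scene, spectrum, dips


def gaussian_smooth(spectrum: Spectrum, fwhm_nm: float) -> Spectrum:
    """Convolve with a Gaussian of the given FWHM (models finite passband).

    Narrow features are attenuated, mirroring how a ~18 nm passband smooths
    high-frequency structure of a wavelength standard.
    """
    sigma_samples = fwhm_nm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / spectrum.grid.step_nm
    vals = gaussian_filter1d(spectrum.values, sigma_samples, mode="nearest")
    return Spectrum(spectrum.grid, vals, spectrum.unit)
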