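"""Wavelength-dependent exposure control.

The adaptive method: measure the per-band efficiency (DN above dark per ms)
from white-reference captures taken on a sparse wavelength stride (default
20 nm), solve the per-band exposure that reaches a target DN subject to a
cap, then densify the sparse solution onto the acquisition grid with a
shape-preserving (monotone cubic Hermite / PCHIP) spline so interpolation
never overshoots the cap between knots.  Bands whose uncapped solution
exceeds the cap are flagged as low-sensitivity.

The target DN is interpreted as signal *above* dark, which makes the solver
invariant to the dark level.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator

from .grids import SpectralGrid, Spectrum, grid_from_wavelengths

__all__ = [
    "EfficiencyCurve",
    "ExposureProfile",
    "characterize_efficiency",
    "model_efficiency_curve",
    "measure_efficiency",
    "solve_exposure",
    "densify_profile",
    "total_acquisition_time",
    "ExposureStrategy",
    "build_profile",
    "TradeoffPoint",
    "exposure_tradeoff_curve",
    "tradeoff_summary",
    "write_profile",
    "read_profile",
]


@dataclass
class EfficiencyCurve:
    """Sampled per-band efficiency: DN above dark per millisecond."""

    wavelengths_nm: np.ndarray
    dn_per_ms: np.ndarray
    reference_exposure_ms: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.dn_per_ms = np.asarray(self.dn_per_ms, dtype=float)
        self.reference_exposure_ms = np.broadcast_to(
            np.asarray(self.reference_exposure_ms, dtype=float),
            self.wavelengths_nm.shape,
        ).copy()
        if self.wavelengths_nm.size == 0:
            raise ValueError("efficiency curve needs at least one sample")
        if np.any(self.dn_per_ms < 0):
            raise ValueError("efficiency must be >= 0")
        order = np.argsort(self.wavelengths_nm)
        self.wavelengths_nm = self.wavelengths_nm[order]
        self.dn_per_ms = self.dn_per_ms[order]
        self.reference_exposure_ms = self.reference_exposure_ms[order]

    def __call__(self, lam) -> np.ndarray:
        """PCHIP evaluation; beyond the outermost knots the end value holds."""
        lam = np.asarray(lam, dtype=float)
        if self.wavelengths_nm.size == 1:
            return np.full(lam.shape, self.dn_per_ms[0])
        clamped = np.clip(lam, self.wavelengths_nm[0], self.wavelengths_nm[-1])
        interp = PchipInterpolator(self.wavelengths_nm, self.dn_per_ms)
        return np.clip(interp(clamped), 0.0, None)


@dataclass
class ExposureProfile:
    """Per-band exposure times with their target DN, cap and capping flags."""

    grid: SpectralGrid
    t_ms: np.ndarray
    target_dn: Optional[float]
    t_max_ms: float
    strategy: str = "custom"
    low_sensitivity_flags: np.ndarray = None

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        if self.t_ms.shape != (self.grid.n_bands,):
            raise ValueError("t_ms must have one entry per grid band")
        if np.any(self.t_ms <= 0):
            raise ValueError("exposures must be > 0")
        if np.any(self.t_ms > self.t_max_ms + 1e-9):
            raise ValueError("exposures exceed the cap t_max_ms")
        if self.low_sensitivity_flags is None:
            self.low_sensitivity_flags = np.zeros(self.grid.n_bands, dtype=bool)
        self.low_sensitivity_flags = np.asarray(self.low_sensitivity_flags, bool)

    @classmethod
    def constant(
        cls, grid: SpectralGrid, t_ms: float, strategy: str = "constant"
    ) -> "ExposureProfile":
        return cls(
            grid=grid,
            t_ms=np.full(grid.n_bands, float(t_ms)),
            target_dn=None,
            t_max_ms=float(t_ms),
            strategy=strategy,
        )

    @property
    def n_capped(self) -> int:
        return int(self.low_sensitivity_flags.sum())


def characterize_efficiency(white_captures, dark_level) -> EfficiencyCurve:
    """Efficiency from white captures: ``(mean DN - dark) / exposure``.

    ``white_captures`` is an iterable of ``(wavelength_nm, mean_dn,
    exposure_ms)``; ``dark_level`` is a DN scalar or one value per capture.
    Captures at or below the dark level are clamped to zero efficiency with
    a warning.
    """
    captures = list(white_captures)
    if not captures:
        raise ValueError("no white captures supplied")
    w = np.array([c[0] for c in captures], dtype=float)
    mean_dn = np.array([c[1] for c in captures], dtype=float)
    t = np.array([c[2] for c in captures], dtype=float)
    if np.any(t <= 0):
        raise ValueError("exposures must be > 0")
    dark = np.broadcast_to(np.asarray(dark_level, dtype=float), w.shape)
    signal = mean_dn - dark
    if np.any(signal < 0):
        warnings.warn(
            "white capture(s) below dark level; efficiency clamped to 0",
            stacklevel=2,
        )
        signal = np.clip(signal, 0.0, None)
    return EfficiencyCurve(w, signal / t, t)


def _knot_grid(grid: SpectralGrid, stride_nm: float) -> SpectralGrid:
    """Characterization sample grid: every ``stride_nm`` across the span."""
    w = grid.wavelengths
    n = int(np.floor((w[-1] - w[0]) / stride_nm)) + 1
    if n < 2:
        raise ValueError("stride too coarse for this grid")
    return SpectralGrid(w[0], w[0] + stride_nm * (n - 1), stride_nm, "closed")


def model_efficiency_curve(
    system, stride_nm: float = 20.0, white_reflectance: float = 0.95
) -> EfficiencyCurve:
    """Noise-free analytic efficiency of a system model (the idealization
    that a long, averaged characterization converges to)."""
    kg = _knot_grid(system.grid, stride_nm)
    eff = np.array(
        [system.efficiency_dn_per_ms(w, white_reflectance) for w in kg.wavelengths]
    )
    return EfficiencyCurve(kg.wavelengths, eff, np.inf)


def measure_efficiency(
    system,
    t_ref_ms: float = 100.0,
    stride_nm: float = 20.0,
    rows: int = 24,
    roi_size: int = 10,
    seed: int = 0,
    noise: bool = True,
    white_reflectance: float = 0.95,
) -> EfficiencyCurve:
    """Simulated characterization: capture a white standard every
    ``stride_nm`` at a reference exposure and derive DN/ms per band.

    A dark capture at the same exposure provides the per-band dark level.
    """
    from .grids import RegionOfInterest, extract_roi_spectrum
    from .scenes import make_flat_scene
    from .simulate import simulate_cube

    kg = _knot_grid(system.grid, stride_nm)
    white_scene = make_flat_scene(kg, white_reflectance, rows=rows, cols=rows)
    dark_scene = make_flat_scene(kg, 0.0, rows=rows, cols=rows)
    profile = ExposureProfile.constant(kg, t_ref_ms, strategy="characterization")
    white = simulate_cube(white_scene, system, profile, seed=seed, noise=noise)
    dark = simulate_cube(dark_scene, system, profile, seed=seed + 1, noise=noise)
    roi = RegionOfInterest(rows // 2, rows // 2, min(roi_size, rows))
    w_mean = extract_roi_spectrum(white, roi).mean.values
    d_mean = extract_roi_spectrum(dark, roi).mean.values
    captures = [
        (lam, m, t_ref_ms) for lam, m in zip(kg.wavelengths, w_mean)
    ]
    return characterize_efficiency(captures, d_mean)


def solve_exposure(
    eff: EfficiencyCurve,
    target_dn: float,
    t_max_ms: float,
    grid: Optional[SpectralGrid] = None,
    saturation_dn: Optional[float] = None,
    strategy: str = "custom",
) -> ExposureProfile:
    """Per-band exposure reaching ``target_dn`` above dark, capped at
    ``t_max_ms``; bands hitting the cap are flagged low-sensitivity."""
    if t_max_ms <= 0:
        raise ValueError("t_max_ms must be > 0")
    if saturation_dn is not None and target_dn >= saturation_dn:
        raise ValueError(
            f"target {target_dn} DN is unreachable without saturation "
            f"(full scale {saturation_dn})"
        )
    if grid is None:
        grid = grid_from_wavelengths(eff.wavelengths_nm)
        e = eff.dn_per_ms.copy()
    else:
        e = eff(grid.wavelengths)
    with np.errstate(divide="ignore"):
        t_uncapped = np.where(e > 0, target_dn / np.where(e > 0, e, 1.0), np.inf)
    # a band whose uncapped solution reaches the cap is already sensitivity
    # limited, so the boundary case is flagged too
    flags = t_uncapped >= t_max_ms - 1e-9
    t = np.minimum(t_uncapped, t_max_ms)
    return ExposureProfile(
        grid=grid,
        t_ms=t,
        target_dn=float(target_dn),
        t_max_ms=float(t_max_ms),
        strategy=strategy,
        low_sensitivity_flags=flags,
    )


def densify_profile(profile: ExposureProfile, grid: SpectralGrid) -> ExposureProfile:
    """Interpolate a sparse (knot) profile onto a dense grid.

    Uses a monotone shape-preserving cubic (PCHIP): the dense profile passes
    through the knots exactly and never overshoots beyond neighboring knot
    values, so the cap cannot be exceeded between knots.  Outside the knot
    span the nearest knot value is held.  The cap is re-applied afterwards
    and capped bands re-flagged.
    """
    knots_w = profile.grid.wavelengths
    if knots_w.size < 2:
        raise ValueError("densification needs at least two knots")
    interp = PchipInterpolator(knots_w, profile.t_ms)
    lam = np.clip(grid.wavelengths, knots_w[0], knots_w[-1])
    t = np.asarray(interp(lam), dtype=float)
    t = np.minimum(t, profile.t_max_ms)
    flags = t >= profile.t_max_ms - 1e-9
    return ExposureProfile(
        grid=grid,
        t_ms=t,
        target_dn=profile.target_dn,
        t_max_ms=profile.t_max_ms,
        strategy=profile.strategy,
        low_sensitivity_flags=flags,
    )


def total_acquisition_time(profile, per_band_overhead_ms: float = 0.0) -> float:
    """Total scan time in seconds: sum of exposures plus per-band overhead.

    Accepts an :class:`ExposureProfile` or any sequence of exposures (an
    empty sequence gives 0 s).
    """
    if per_band_overhead_ms < 0:
        raise ValueError("overhead must be >= 0")
    t = profile.t_ms if isinstance(profile, ExposureProfile) else np.asarray(
        profile, dtype=float
    )
    return float((t.sum() + t.size * per_band_overhead_ms) / 1000.0)


@dataclass
class ExposureStrategy:
    """Named acquisition strategy: constant exposure or capped adaptive."""

    name: str
    kind: str  # constant | short_limit | long_limit | custom
    t_constant_ms: float = 250.0
    t_max_ms: float = 500.0
    target_dn: float = 700.0
    stride_nm: float = 20.0
    t_ref_ms: float = 100.0

    @classmethod
    def constant(cls, t_ms: float = 250.0) -> "ExposureStrategy":
        return cls("constant", "constant", t_constant_ms=t_ms)

    @classmethod
    def short_limit(cls, t_max_ms: float = 500.0, **kw) -> "ExposureStrategy":
        return cls("short_limit", "short_limit", t_max_ms=t_max_ms, **kw)

    @classmethod
    def long_limit(cls, t_max_ms: float = 1200.0, **kw) -> "ExposureStrategy":
        return cls("long_limit", "long_limit", t_max_ms=t_max_ms, **kw)


def build_profile(
    strategy: ExposureStrategy, system, seed: int = 0, noise: bool = True
) -> ExposureProfile:
    """Realize a strategy on a system: characterize, solve, densify."""
    if strategy.kind == "constant":
        return ExposureProfile.constant(
            system.grid, strategy.t_constant_ms, strategy=strategy.name
        )
    eff = measure_efficiency(
        system,
        t_ref_ms=strategy.t_ref_ms,
        stride_nm=strategy.stride_nm,
        seed=seed,
        noise=noise,
    )
    knots = solve_exposure(
        eff,
        strategy.target_dn,
        strategy.t_max_ms,
        saturation_dn=system.sensor.max_dn,
        strategy=strategy.name,
    )
    return densify_profile(knots, system.grid)


@dataclass
class TradeoffPoint:
    strategy: str
    time_s: float
    rmse_pct: float
    profile: ExposureProfile


def exposure_tradeoff_curve(
    system,
    scene,
    truth: Spectrum,
    strategies: Sequence[ExposureStrategy],
    seed: int = 0,
    roi_size: int = 10,
    noise: bool = True,
    replicates: int = 3,
) -> List[TradeoffPoint]:
    """RMSE-versus-time trade-off across exposure strategies.

    For each strategy: build its profile, run ``replicates`` acquisitions, calibrate each, extract the
    center-ROI mean spectrum and score it against the scene's generating
    ground truth; the reported RMSE is the mean over replicate captures
    (replicate acquisitions of a static standard are cheap and reduce the
    variance of the fidelity estimate).
    """
    from .calibrate import calibrate_reflectance
    from .grids import RegionOfInterest
    from .metrics import rmse
    from .scenes import make_flat_scene
    from .simulate import simulate_cube

    n_seeds = 1 + 3 * replicates
    seeds = (
        np.random.SeedSequence(seed).generate_state(n_seeds * len(strategies))
        & 0x7FFFFFFF
    )
    white_scene = make_flat_scene(system.grid, 0.95, rows=scene.rows, cols=scene.cols)
    dark_scene = make_flat_scene(system.grid, 0.0, rows=scene.rows, cols=scene.cols)
    roi = RegionOfInterest(
        scene.rows // 2, scene.cols // 2, min(roi_size, scene.rows, scene.cols)
    )
    points: List[TradeoffPoint] = []
    for i, strat in enumerate(strategies):
        block = [int(s) for s in seeds[n_seeds * i : n_seeds * (i + 1)]]
        profile = build_profile(strat, system, seed=block[0], noise=noise)
        errors = []
        for r in range(replicates):
            s_white, s_dark, s_target = block[1 + 3 * r : 4 + 3 * r]
            white = simulate_cube(
                white_scene, system, profile, seed=s_white, noise=noise
            )
            dark = simulate_cube(dark_scene, system, profile, seed=s_dark, noise=noise)
            target = simulate_cube(scene, system, profile, seed=s_target, noise=noise)
            refl = calibrate_reflectance(
                target, white, dark, white_reflectance=0.95
            )
            errors.append(rmse(truth, refl.roi_mean(roi)))
        points.append(
            TradeoffPoint(
                strategy=strat.name,
                time_s=total_acquisition_time(profile),
                rmse_pct=float(np.mean(errors)),
                profile=profile,
            )
        )
    return points


def tradeoff_summary(points, baseline: str = "constant") -> dict:
    """Relative RMSE reductions and reduction-per-added-second vs a baseline.

    ``points`` may be :class:`TradeoffPoint` objects or ``(name, time_s,
    rmse_pct)`` triples.
    """
    triples = [
        (p.strategy, p.time_s, p.rmse_pct)
        if isinstance(p, TradeoffPoint)
        else tuple(p)
        for p in points
    ]
    by_name = {name: (time_s, r) for name, time_s, r in triples}
    if baseline not in by_name:
        raise ValueError(f"baseline {baseline!r} not among {sorted(by_name)}")
    t0, r0 = by_name[baseline]
    out = {}
    for name, (t, r) in by_name.items():
        if name == baseline:
            continue
        rel = 100.0 * (r0 - r) / r0
        extra_s = t - t0
        out[name] = {
            "rmse_pct": r,
            "time_s": t,
            "relative_rmse_reduction_pct": rel,
            "extra_time_s": extra_s,
            "reduction_pct_per_second": rel / extra_s if extra_s > 0 else np.inf,
        }
    out[baseline] = {"rmse_pct": r0, "time_s": t0}
    return out


def write_profile(path, profile: ExposureProfile) -> None:
    """Two-column text (wavelength nm, exposure ms) with a JSON metadata line."""
    import json

    meta = {
        "target_dn": profile.target_dn,
        "t_max_ms": profile.t_max_ms,
        "strategy": profile.strategy,
        "grid": profile.grid.to_dict(),
        "low_sensitivity_flags": [bool(f) for f in profile.low_sensitivity_flags],
    }
    lines = ["# " + json.dumps(meta, sort_keys=True)]
    lines += [
        f"{w:.3f}\t{t:.6f}"
        for w, t in zip(profile.grid.wavelengths, profile.t_ms)
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_profile(path) -> ExposureProfile:
    import json

    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    meta = json.loads(lines[0].lstrip("# "))
    t = np.array([float(ln.split()[1]) for ln in lines[1:]])
    return ExposureProfile(
        grid=SpectralGrid.from_dict(meta["grid"]),
        t_ms=t,
        target_dn=meta["target_dn"],
        t_max_ms=meta["t_max_ms"],
        strategy=meta["strategy"],
        low_sensitivity_flags=np.array(meta["low_sensitivity_flags"], dtype=bool),
    )
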