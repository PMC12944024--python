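"""End-to-end experiment orchestration and seeded fixture generation.

Each named experiment is a synthetic counterpart of one hardware study:

* ``rfs_vs_efs``             -- emission- vs reception-path filtering:
  throughput deficit, matched exposures, spectral fidelity of both setups,
* ``exposure_strategies``    -- constant vs capped adaptive exposure:
  RMSE/time trade-off,
* ``system_characterization``-- adaptive exposure on the clinical preset,
  checker + wavelength-standard captures, full QC metric report,
* ``system_comparison``      -- clinical preset vs the spatio-spectral
  comparison system, side-by-side table,
* ``motion_analysis``        -- inter-band RMSE vs motion amplitude for the
  spatio-spectral scan against the static spectral scan.

A run directory contains a machine-readable manifest (config + hash + seed +
version), the report JSON, exposure profiles and a plain-text log; the same
config and seed reproduce all of it byte-identically.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, List, Optional

import numpy as np
import yaml

from . import __version__
from .calibrate import calibrate_reflectance
from .envi import write_cube
from .exposure import (
    ExposureStrategy,
    build_profile,
    densify_profile,
    exposure_tradeoff_curve,
    ExposureProfile,
    model_efficiency_curve,
    measure_efficiency,
    solve_exposure,
    total_acquisition_time,
    tradeoff_summary,
    write_profile,
)
from .grids import RegionOfInterest, extract_roi_spectrum
from .metrics import (
    CharacterizationReport,
    compare_systems,
    dynamic_range,
    interband_rmse,
    oecf,
    rmse,
    snr,
)
from .optics import SYSTEM_PRESETS, matched_exposure
from .scenes import (
    GRAYSCALE_REFLECTANCES,
    make_flat_scene,
    make_rezchecker_scene,
    make_zenith_like_reference,
    make_zenith_scene,
)
from .simulate import MotionModel, inject_filter_transition, simulate_cube, \
    simulate_spatioscan_cube

__all__ = ["RunConfig", "run_experiment", "generate_fixtures", "EXPERIMENTS"]


@dataclass
class RunConfig:
    """Configuration of one experiment run."""

    experiment: str
    seed: int = 0
    out_dir: str = "runs"
    system: Optional[str] = None
    options: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _seeds(seed: int, n: int) -> List[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) & 0x7FFFFFFF]


def _system(name: str):
    if name not in SYSTEM_PRESETS:
        raise KeyError(
            f"unknown system preset {name!r}; valid: {sorted(SYSTEM_PRESETS)}"
        )
    return SYSTEM_PRESETS[name]()


# ---------------------------------------------------------------------------
# Experiments
# ---------------------------------------------------------------------------

def _exp_rfs_vs_efs(cfg: RunConfig, log: List[str]) -> dict:
    efs = _system("efs_lab")
    rfs = _system("rfs_lab")
    target = cfg.options.get("target_dn", 700.0)
    s_zen, s1, s2, s3, s4, s5, s6 = _seeds(cfg.seed, 7)

    # Idealized (noise-free) exposure solutions: the reception path receives
    # 87.5% less light, so every uncapped band needs exactly 8x the exposure.
    eff_e = model_efficiency_curve(efs)
    eff_r = model_efficiency_curve(rfs)
    cap = cfg.options.get("t_max_ms", 1e6)
    prof_e = solve_exposure(eff_e, target, cap, grid=efs.grid)
    prof_r = solve_exposure(eff_r, target, cap, grid=rfs.grid)
    uncapped = ~(prof_e.low_sensitivity_flags | prof_r.low_sensitivity_flags)
    ratio = prof_r.t_ms[uncapped] / prof_e.t_ms[uncapped]
    matched_ms = matched_exposure(efs, rfs, 850.0, 250.0)
    deficit_pct = 100.0 * (1.0 - rfs.throughput / efs.throughput)
    log.append(
        f"solved exposure ratio RFS/EFS over {int(uncapped.sum())} uncapped "
        f"bands: mean {ratio.mean():.6f}"
    )

    # Noisy end-to-end fidelity comparison on the wavelength standard.
    results = {}
    for system, cap_ms, seeds in (
        (efs, 1000.0, (s1, s2, s3)),
        (rfs, 8000.0, (s4, s5, s6)),
    ):
        scene, truth, _ = make_zenith_scene(system.grid, seed=s_zen, rows=24, cols=24)
        strat = ExposureStrategy(
            name=f"{system.name}_adaptive", kind="short_limit",
            t_max_ms=cap_ms, target_dn=target, t_ref_ms=100.0,
        )
        profile = build_profile(strat, system, seed=seeds[0])
        white = simulate_cube(
            make_flat_scene(system.grid, 0.95, 24, 24), system, profile, seeds[1]
        )
        dark = simulate_cube(
            make_flat_scene(system.grid, 0.0, 24, 24), system, profile, seeds[1] + 1
        )
        raw = simulate_cube(scene, system, profile, seeds[2])
        refl = calibrate_reflectance(raw, white, dark, white_reflectance=0.95)
        measured = refl.roi_mean(RegionOfInterest(12, 12, 10))
        results[system.name] = {
            "rmse_pct": rmse(truth, measured),
            "total_time_s": total_acquisition_time(profile),
            "n_capped": profile.n_capped,
        }
    return {
        "throughput_deficit_pct": deficit_pct,
        "matched_exposure_ms_from_250": matched_ms,
        "exposure_ratio_uncapped": {
            "mean": float(ratio.mean()),
            "min": float(ratio.min()),
            "max": float(ratio.max()),
            "n_bands": int(uncapped.sum()),
        },
        "fidelity": results,
    }


def _exp_exposure_strategies(cfg: RunConfig, log: List[str]) -> dict:
    system = _system(cfg.system or "efs_lab")
    target = cfg.options.get("target_dn", 700.0)
    s_zen, s_curve = _seeds(cfg.seed, 2)
    scene, truth, _ = make_zenith_scene(system.grid, seed=s_zen, rows=24, cols=24)
    strategies = [
        ExposureStrategy.constant(cfg.options.get("t_constant_ms", 250.0)),
        ExposureStrategy.short_limit(
            cfg.options.get("short_cap_ms", 500.0), target_dn=target
        ),
        ExposureStrategy.long_limit(
            cfg.options.get("long_cap_ms", 1200.0), target_dn=target
        ),
    ]
    points = exposure_tradeoff_curve(
        system, scene, truth, strategies, seed=s_curve
    )
    for p in points:
        log.append(f"{p.strategy}: {p.time_s:.1f} s, RMSE {p.rmse_pct:.2f}%")
    return {
        "points": [
            {"strategy": p.strategy, "time_s": p.time_s, "rmse_pct": p.rmse_pct}
            for p in points
        ],
        "summary": tradeoff_summary(points),
    }


def _characterize(
    system,
    seed: int,
    target_dn: float,
    t_max_ms: float,
    apply_transition: bool,
    log: List[str],
    save_cubes: Optional[Path] = None,
):
    """Shared characterization pipeline; returns (report, detail dict)."""
    s_char, s_w, s_d, s_rez, s_zen, s_zenc = _seeds(seed, 6)
    eff = measure_efficiency(system, t_ref_ms=50.0, stride_nm=20.0, seed=s_char)
    knots = solve_exposure(
        eff, target_dn, t_max_ms, saturation_dn=system.sensor.max_dn,
        strategy="short_limit",
    )
    profile = densify_profile(knots, system.grid)
    log.append(
        f"{system.name}: {profile.n_capped}/{system.grid.n_bands} bands capped "
        f"at {t_max_ms:g} ms"
    )

    scene = make_rezchecker_scene(system.grid)
    zen_spec, _ = make_zenith_like_reference(system.grid, seed=s_zen)
    zen_scene = make_flat_scene(
        system.grid, zen_spec, rows=scene.rows, cols=scene.cols
    )
    white_scene = make_flat_scene(system.grid, 0.95, scene.rows, scene.cols)
    dark_scene = make_flat_scene(system.grid, 0.0, scene.rows, scene.cols)
    white = simulate_cube(white_scene, system, profile, s_w)
    dark = simulate_cube(dark_scene, system, profile, s_d)
    rez = simulate_cube(scene, system, profile, s_rez)
    zen = simulate_cube(zen_scene, system, profile, s_zenc)
    transition_note = None
    if apply_transition and system.filter_transition is not None:
        lo, hi, mag = system.filter_transition
        rez = inject_filter_transition(rez, (lo, hi), mag)
        zen = inject_filter_transition(zen, (lo, hi), mag)
        transition_note = (
            f"filter hand-off artefact injected over {lo:g}-{hi:g} nm "
            f"(x{mag:g})"
        )
        log.append(transition_note)

    rez_refl = calibrate_reflectance(rez, white, dark, white_reflectance=0.95)
    zen_refl = calibrate_reflectance(zen, white, dark, white_reflectance=0.95)

    # Spectral fidelity against the generating truth of the standard.
    measured = zen_refl.roi_mean(
        RegionOfInterest(scene.rows // 2, scene.cols // 2, 10)
    )
    rmse_pct = rmse(zen_spec, measured)

    # DR / SNR from the raw checker DN: bright 95% tile vs darkest tile.
    bright = extract_roi_spectrum(rez, scene.roi_for("gray01"))
    darkest = extract_roi_spectrum(rez, scene.roi_for("gray12"))
    dr = dynamic_range(bright.mean, darkest.mean)
    s = snr(bright.mean, darkest.sd)

    # OECF from calibrated grayscale tiles, per band.
    tiles = np.stack(
        [
            rez_refl.roi_mean(scene.roi_for(f"gray{i + 1:02d}")).values
            for i in range(12)
        ]
    )
    oe = oecf(GRAYSCALE_REFLECTANCES, tiles)

    inter = interband_rmse(rez_refl)
    avg_fwhm = float(
        np.mean([system.channel_for(w).passband.fwhm(w) for w in system.grid.wavelengths])
    )
    notes = ["dark role for DR/SNR: darkest grayscale tile (nominal 24%)"]
    if transition_note:
        notes.append(transition_note)
    report = CharacterizationReport(
        system_name=system.name,
        spatial_resolution=(scene.rows, scene.cols),
        spectral_range_nm=(system.grid.wavelengths[0], system.grid.wavelengths[-1]),
        n_bands=system.grid.n_bands,
        avg_fwhm_nm=avg_fwhm,
        rmse_pct=rmse_pct,
        dr=dr,
        snr=s,
        oecf=oe,
        interband=inter,
        total_time_s=total_acquisition_time(profile),
        wavelengths_nm=system.grid.wavelengths,
        notes=notes,
    )
    if save_cubes is not None:
        write_cube(save_cubes / f"{system.name}_rezchecker", rez)
        write_cube(save_cubes / f"{system.name}_white", white)
        write_cube(save_cubes / f"{system.name}_dark", dark)
    return report, profile


def _exp_system_characterization(cfg: RunConfig, log: List[str]) -> dict:
    system = _system(cfg.system or "clinical_lctf")
    target = cfg.options.get("target_dn", 3000.0)
    cap = cfg.options.get("t_max_ms", 300.0)
    apply_transition = cfg.options.get("filter_transition", True)
    out = Path(cfg.out_dir) / cfg.experiment if cfg.options.get("save_cubes") else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    report, profile = _characterize(
        system, cfg.seed, target, cap, apply_transition, log, save_cubes=out
    )
    d = report.to_dict()
    d["profile"] = {
        "t_ms": [float(t) for t in profile.t_ms],
        "n_capped": profile.n_capped,
        "target_dn": profile.target_dn,
        "t_max_ms": profile.t_max_ms,
    }
    return d


def _exp_system_comparison(cfg: RunConfig, log: List[str]) -> dict:
    s1, s2 = _seeds(cfg.seed, 2)
    rep_a, _ = _characterize(
        _system("clinical_lctf"), s1, 3000.0, 300.0, True, log
    )
    rep_b, _ = _characterize(
        _system("snapscan_like"), s2,
        cfg.options.get("target_dn_b", 700.0),
        cfg.options.get("t_max_ms_b", 300.0),
        False, log,
    )
    table = compare_systems([rep_a, rep_b])
    return {
        "table": json.loads(table.to_json()),
        "reports": [rep_a.to_dict(), rep_b.to_dict()],
    }


def _exp_motion_analysis(cfg: RunConfig, log: List[str]) -> dict:
    system = _system(cfg.system or "snapscan_like")
    amplitudes = cfg.options.get("amplitudes_px", [0, 1, 2, 4])
    t_ms = cfg.options.get("t_constant_ms", 100.0)
    s_w, s_d, s_static, s_motion = _seeds(cfg.seed, 4)
    scene = make_rezchecker_scene(system.grid)
    profile = ExposureProfile.constant(system.grid, t_ms)
    white = simulate_cube(
        make_flat_scene(system.grid, 0.95, scene.rows, scene.cols),
        system, profile, s_w,
    )
    dark = simulate_cube(
        make_flat_scene(system.grid, 0.0, scene.rows, scene.cols),
        system, profile, s_d,
    )
    static = simulate_cube(scene, system, profile, s_static)
    static_mean = interband_rmse(
        calibrate_reflectance(static, white, dark, white_reflectance=0.95)
    ).mean_pct
    results = {}
    for amp in amplitudes:
        cube = simulate_spatioscan_cube(
            scene, system, profile, MotionModel(amplitude_px=float(amp)),
            seed=s_motion,
        )
        refl = calibrate_reflectance(cube, white, dark, white_reflectance=0.95)
        results[str(amp)] = interband_rmse(refl).mean_pct
        log.append(f"amplitude {amp} px: mean inter-band RMSE {results[str(amp)]:.3f}%")
    return {
        "static_spectral_scan_pct": static_mean,
        "spatioscan_by_amplitude_pct": results,
    }


EXPERIMENTS: Dict[str, Callable] = {
    "rfs_vs_efs": _exp_rfs_vs_efs,
    "exposure_strategies": _exp_exposure_strategies,
    "system_characterization": _exp_system_characterization,
    "system_comparison": _exp_system_comparison,
    "motion_analysis": _exp_motion_analysis,
}


def run_experiment(config: RunConfig) -> Path:
    """Run a named experiment; returns the output directory.

    Writes ``manifest.json`` (config, config hash, seed, version),
    ``report.json`` and ``log.txt``.  Identical config and seed produce
    byte-identical outputs.
    """
    if config.experiment not in EXPERIMENTS:
        raise KeyError(
            f"unknown experiment {config.experiment!r}; valid: "
            f"{sorted(EXPERIMENTS)}"
        )
    out = Path(config.out_dir) / config.experiment
    out.mkdir(parents=True, exist_ok=True)
    log: List[str] = [f"experiment={config.experiment} seed={config.seed}"]
    report = EXPERIMENTS[config.experiment](config, log)
    # hash the scientific configuration only: where outputs land must not
    # change what is computed
    hashed = {k: v for k, v in config.to_dict().items() if k != "out_dir"}
    cfg_json = json.dumps(hashed, sort_keys=True)
    manifest = {
        "experiment": config.experiment,
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": config.seed,
        "colposim_version": __version__,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=2))
    (out / "report.json").write_text(json.dumps(report, sort_keys=True, indent=2))
    (out / "log.txt").write_text("\n".join(log) + "\n")
    return out


def generate_fixtures(seed: int, out_dir) -> List[Path]:
    """Write seeded synthetic fixtures: wavelength-standard spectrum (with
    ground-truth dips), checker scene description, system preset summaries
    and a small demo cube with white/dark references.  Same seed, same bytes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: List[Path] = []
    s_zen, s_demo, s_w, s_d = _seeds(seed, 4)

    from .optics import clinical_dual_lctf

    system = clinical_dual_lctf()
    grid = system.grid

    spec, dips = make_zenith_like_reference(grid, seed=s_zen)
    p = out / "zenith_like_reference.txt"
    p.write_text(
        "# wavelength_nm\treflectance (synthetic wavelength-standard stand-in)\n"
        + "\n".join(
            f"{w:.1f}\t{v:.6f}" for w, v in zip(spec.wavelengths, spec.values)
        )
        + "\n"
    )
    paths.append(p)
    p = out / "zenith_like_dips.json"
    p.write_text(
        json.dumps(
            [dataclasses.asdict(d) for d in dips], sort_keys=True, indent=2
        )
    )
    paths.append(p)

    scene = make_rezchecker_scene(grid)
    p = out / "rezchecker_scene.json"
    p.write_text(
        json.dumps(
            {
                "rows": scene.rows,
                "cols": scene.cols,
                "grid": grid.to_dict(),
                "patches": [
                    {
                        "label": pa.label,
                        "row0": pa.row0,
                        "col0": pa.col0,
                        "height": pa.height,
                        "width": pa.width,
                        "reflectance": [round(float(v), 6) for v in pa.reflectance.values],
                    }
                    for pa in scene.patches
                ],
            },
            sort_keys=True,
        )
    )
    paths.append(p)

    presets = {
        name: {
            "grid": fn().grid.to_dict(),
            "bit_depth": fn().sensor.bit_depth,
            "throughput": fn().throughput,
            "mode": fn().mode,
        }
        for name, fn in SYSTEM_PRESETS.items()
    }
    p = out / "system_presets.yaml"
    p.write_text(yaml.safe_dump(presets, sort_keys=True))
    paths.append(p)

    profile = ExposureProfile.constant(grid, 150.0)
    demo_scene = make_flat_scene(grid, 0.5, rows=16, cols=16)
    demo = simulate_cube(demo_scene, system, profile, seed=s_demo)
    white = simulate_cube(
        make_flat_scene(grid, 0.95, 16, 16), system, profile, seed=s_w
    )
    darkc = simulate_cube(
        make_flat_scene(grid, 0.0, 16, 16), system, profile, seed=s_d
    )
    paths.append(write_cube(out / "demo_flat50", demo))
    paths.append(write_cube(out / "demo_white", white))
    paths.append(write_cube(out / "demo_dark", darkc))
    return paths
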