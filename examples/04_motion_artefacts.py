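"""Motion sensitivity of spatio-spectral scanning vs spectral scanning.

A spatio-spectral scanner assembles each band from frames taken at different
times, so scene motion misaligns consecutive bands; a tunable-filter
spectral scanner captures each band in one frame and is insensitive to slow
drift.  The inter-band RMSE statistic quantifies this.
"""
import colposim as cs

system = cs.snapscan_like()
scene = cs.make_rezchecker_scene(system.grid)
profile = cs.ExposureProfile.constant(system.grid, 100.0)

white = cs.simulate_cube(
    cs.make_flat_scene(system.grid, 0.95, scene.rows, scene.cols),
    system, profile, seed=10,
)
dark = cs.simulate_cube(
    cs.make_flat_scene(system.grid, 0.0, scene.rows, scene.cols),
    system, profile, seed=11,
)

static = cs.simulate_cube(scene, system, profile, seed=12)
static_rmse = cs.interband_rmse(
    cs.calibrate_reflectance(static, white, dark, white_reflectance=0.95)
).mean_pct
print(f"static spectral scan : mean inter-band RMSE {static_rmse:6.2f}%")

for amp in (0, 1, 2, 4):
    cube = cs.simulate_spatioscan_cube(
        scene, system, profile, cs.MotionModel(amplitude_px=float(amp)), seed=13
    )
    refl = cs.calibrate_reflectance(cube, white, dark, white_reflectance=0.95)
    rmse = cs.interband_rmse(refl).mean_pct
    print(f"spatio-spectral scan, drift {amp} px/frame: "
          f"mean inter-band RMSE {rmse:6.2f}%")

print("\nZero motion reproduces the static statistic; any drift misaligns")
print("consecutive bands and the inter-band error grows with amplitude —")
print("the signature used to flag motion-corrupted clinical cubes.")
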