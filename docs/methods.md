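# Methods

## Radiometric forward model

The expected digital number for a band tuned to center `c`, exposure `t`
(ms) and scene reflectance `R` is

    DN(R, c, t) = clip( d₀ + d₁·t + g · Φ · τ · t · R · ∫ E(λ) T(λ; c) QE(λ) dλ ,
                        0, 2^b − 1 )

with illuminant relative power `E`, passband transmission `T`, sensor
quantum efficiency `QE`, throughput `τ`, gain `g` (DN per photoelectron),
dark offset/rate `d₀, d₁` and flux scale `Φ` (photoelectrons per unit band
integral per ms). Below saturation the signal above dark is exactly affine
in both `t` and `R`; that linearity is what makes target-DN exposure
solving and flat-field calibration consistent, and it is asserted
numerically in the tests.

Absolute radiometry is deliberately abstracted: `Φ` folds the photon-flux
scale into DN/ms, because the quantities of interest (exposure ratios,
reflectance, dB metrics) are all ratios. The band integral is evaluated by
trapezoidal quadrature on a fine local grid (±6σ for Gaussian passbands;
the exact support for rectangular ones, where it reproduces the closed form
to numerical precision). Out-of-band leakage enters as a small constant
floor integrated over the illuminant support.

Noise per voxel: Poisson shot noise in photoelectrons, Gaussian read noise
(electrons RMS), deterministic dark signal, rounding to integer DN and
clipping to the bit depth. The predicted per-pixel DN variance
`g²(n_e + r²) + 1/12` is verified against sample variances with a χ² test.
Draw order is fixed (bands in grid order, per band one Poisson then one
Gaussian draw over the frame), so one integer seed reproduces any cube
bit-exactly.

## Instrument presets

Two grid conventions are first-class because both appear in practice for
the same nominal range: `closed` (both endpoints, 460–1000 nm @ 5 nm → 109
bands) and `half_open` (endpoint excluded, 650–1100 nm @ 5 nm → 90 bands).

* `efs_lab` / `rfs_lab` — laboratory NIR setup, 90 bands, 10-bit sensor
  with QE 60% near 600 nm falling to 5% at 1000 nm, halogen source
  (relative Planck spectrum at 3200 K), Gaussian passband with FWHM ramping
  9 → 24 nm across the filter range. The reception-filtering variant is
  identical except `τ` is 12.5% of the emission variant — the 87.5% light
  deficit that maps a 250 ms exposure to 2000 ms.
* `clinical_lctf` — dual-filter clinical system, 109 bands, 12-bit sensor
  (QE 72% over 525–580 nm, read noise 2.5 e⁻, dark offset 40 DN). Band
  centers below 720 nm use a high-CRI LED channel (near-uniform 420–700 nm
  with soft roll-off), the rest a halogen channel; the hand-off between the
  two optical paths is modeled as a multiplicative perturbation (default
  ×1.15) on the bands with centers in 720–740 nm, applied by
  `inject_filter_transition` and flagged in cube metadata. No functional
  form for this artefact is established, so the simplest band-local
  multiplicative model is used.
* `snapscan_like` — spatio-spectral comparison system, 87 bands over
  470–900 nm, 10-bit, with strongly oscillating per-band sensitivity
  (mosaic-style QE with a deep 600–650 nm dip). It exists to exhibit the
  two weaknesses the tunable-filter design addresses: non-uniform SNR and
  motion sensitivity.

Flux scales are chosen once per preset so the operating points are the
realistic ones: the lab system reaches a 700 DN target at ≈250 ms at its
peak efficiency (so the constant-exposure baseline and the adaptive profile
coincide at the peak), and the clinical system reaches 3000 DN in
150–250 ms through the visible while the NIR tail hits the 300 ms cap.

## Spatio-spectral scanning and motion

Output bands are assembled from per-frame diagonal spatial–spectral planes
by nearest-frame assignment: for band `b`, rows in the first image half
take the scene state at frame `b`, the second half at frame `b+1`. Scene
motion is an integer-pixel periodic shift per frame, either constant drift
or a seeded Gaussian random walk. Zero amplitude reproduces the static
spectral scan bit-exactly at the same seed. This is the simplest model that
yields the observed phenomenology — band-to-band edge displacement equal to
the per-frame drift and inter-band RMSE increasing with amplitude — and it
makes no claim about any particular scan camera's internals.

## Exposure control

`characterize_efficiency` converts white captures to DN-above-dark per ms;
the target DN is interpreted as signal above dark, which makes the solver
invariant to the dark level (the alternative — target as absolute DN —
would couple the solution to the dark offset for no physical reason).
`solve_exposure` applies `t(λ) = min(target/e(λ), t_max)` and flags bands
whose uncapped solution reaches the cap (zero-efficiency bands get the cap
and the flag). `densify_profile` interpolates sparse knot solutions with a
monotone shape-preserving cubic (PCHIP) rather than a natural cubic spline:
between knots a natural spline can overshoot the cap (e.g. knots
100/300/280 ms), while PCHIP is bounded by neighboring knot values; the cap
is re-applied after interpolation regardless. Outside the knot span the
nearest knot value is held. Characterization default stride is 20 nm (23
knots over a 650–1090 nm span), reference exposure chosen to stay well
below saturation.

`exposure_tradeoff_curve` scores each strategy by simulating full
acquisitions (white, dark, target), calibrating, extracting the center-ROI
mean spectrum and computing percent RMSE against the scene's generating
truth. The reported RMSE is the mean over 3 independent replicate
acquisitions by default: a single noisy draw of a ~0.1% difference is not a
stable estimate of a strategy's expected fidelity, and replicate captures
of a static standard are the cheap, standard way to estimate it. Per-band
overhead defaults to 0 ms and is configurable; real totals include
hardware settling times that are not modeled.

## Calibration

`R = R_w (raw − dark)/(white − dark)` per voxel and band, with `R_w` the
known reflectance of the white standard (default 1.0; the simulator's
panel is 0.95 and the pipelines pass that). Voxels with
`white − dark ≤ 1 DN` or with saturated raw/white are masked invalid and
zero-filled rather than clipped, so downstream statistics can exclude them
explicitly. Reflectance slightly above 1 from noise is retained (exposed
via `overshoot_mask`), keeping RMSE statistics unbiased. White/dark may be
full cubes or per-band ROI-mean spectra broadcast spatially; both
conventions occur in practice and both are supported.

## Metrics

* **Spectral RMSE** is computed on reflectance fractions and reported ×100,
  percent of the reflectance scale. Grid mismatches require explicit
  opt-in to linear resampling of the reference onto the measurement grid.
* **DR and SNR** are `20·log₁₀` ratios per band; the global value is the
  unweighted mean over bands with positive denominators (excluded bands
  warn). The bright patch is the 95% grayscale tile; the dark-current
  proxy is the darkest available tile (nominal 24%) — step charts differ in
  their darkest step, so reports carry an explicit note of this role
  assignment.
* **OECF**: points are (status T density `D = −log₁₀ R_nominal`, measured
  mean reflectance) per tile per band. An ideal linear system lies exactly
  on the reference curve `R = 10^−D`, so the primary deviation statistic is
  the maximum absolute residual from that curve (exactly zero for a perfect
  response). Because reflectance vs density is exponential, a least-squares
  *line* has nonzero residuals even for a perfect system; the line residual
  and R² are therefore reported as secondary descriptive statistics, not as
  the deviation.
* **Inter-band RMSE**: per-pixel RMS difference between each band and its
  predecessor, averaged into one scalar; computed on calibrated reflectance
  by default (a raw-DN mode normalizes by full scale). Sensitive to
  band-to-band misalignment, hence the motion statistic.
* **ROI statistics** use the population SD (ddof = 0), the common
  imaging-QC convention; saturated voxels inside an ROI are counted and
  reported, not silently dropped.

## Synthetic data: what it does and does not emulate

The scene generators emulate *structure*, not any specific product: the
checker target has 42 deterministic color patches and a central 12-tile
grayscale spanning 0.95 → 0.24; the wavelength standard is a smooth
baseline with 4 seeded Gaussian absorption dips (depth 0.15–0.35, σ 3–8 nm,
≥40 nm apart) whose ground truth is returned for dip-recovery and
passband-smoothing checks. Real reference materials have proprietary
spectra, spatial non-uniformity, specular components and wavelength
calibration error, none of which are modeled. Consequently, passing tests
demonstrate the *relations* the method relies on — exposure scaling with
throughput, strategy orderings, motion orderings, metric closed forms,
calibration consistency — not the absolute RMSE/DR/SNR values any physical
instrument would report; those depend on unpublished device curves and
reference spectra and are outside what a simulation can reproduce.

## Numerical choices and degenerate inputs

* Grid spans must divide the step exactly (tolerance 10⁻⁹ relative); the
  error names the remainder.
* PCHIP evaluation clamps beyond the outermost knots (hold-nearest).
* ε = 1 DN stability threshold in calibration; division never sees a
  near-zero denominator.
* Min–max normalization of a constant spectrum is an error, not a NaN.
* dB metrics exclude non-positive denominators band-wise with a warning
  instead of failing the whole series.
* A band whose uncapped exposure equals the cap exactly is flagged
  low-sensitivity (boundary counts as capped).
* Problem sizes in tests and the acceptance script (24×24 to 48×48 frames,
  87–109 bands, 3–8 replicates) were chosen as the smallest sizes at which
  the estimated quantities are stable; all simulations complete in seconds.

## Known limitations

Physical optics (diffraction, polarization inside the filter, stray light,
chromatic aberration), spatial illumination non-uniformity, per-pixel
response non-uniformity and closed-loop live exposure adjustment are out of
scope. The spatio-spectral model is a two-plane nearest-frame idealization.
ENVI I/O covers exactly the BSQ/uint16 layout the package writes, with a
JSON sidecar for metadata the ENVI header does not standardize.
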