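# memfluct

Membrane fluctuation tension mapping and companion analytics for correlative
interference/fluorescence imaging studies, exercised end-to-end on synthetic
data with known ground truth.

The package covers four analysis tracks plus the generators that feed them:

- **`memfluct.synthetic`** — seeded generators for every pipeline input:
  stationary Gaussian height-fluctuation series with a prescribed model
  spectrum (random-phase spectral synthesis), pixel-wise tension-field
  movies, Gaussian-spot fluorescence frames, dual-channel endosome/actin
  z-stacks with controlled object overlap and an optional cortical ring,
  Guinier-type scattering profiles (with optional low-angle interparticle
  suppression) and diffusion autocorrelation curves.
- **`memfluct.mechanics`** — intensity→height calibration from a large-bead
  interference profile, first-branch region screening, PSD estimation
  (Welch-style periodogram averaging and a covariance-method autoregressive
  estimator), evaluation and fitting of the overdamped-membrane fluctuation
  spectrum

  ```
  PSD(f) = (4 η_eff A k_B T / π) ∫_{q_min}^{q_max} dq /
           [ (4 η_eff · 2πf)² + (κq³ + σq + γ/q)² ]
  ```

  for tension σ, confinement γ, effective viscosity η_eff and active
  multiplier A (κ, T, q-range held), SD_time computation, and filtered
  pixel-wise tension maps (validity: r² > 0.9, σ < 5,000 pN/μm,
  SD_time < 15 nm; configurable).

  *Note:* the published rendering of the spectrum is typographically
  ambiguous in the confinement term; it is implemented as `γ/q` inside the
  squared bracket, following the standard fluctuation framework.

  *Note:* a single short spectrum cannot constrain σ with η_eff **and** A
  simultaneously free (near-degenerate scaling direction), so per-series and
  per-pixel tension estimation holds those two at calibration values
  (`DEFAULT_NUISANCE_CALIBRATION`; override with `fix={}` for the all-free
  fit, which is reserved for well-conditioned/noiseless spectra).
- **`memfluct.profiling`** — integer-translation frame registration by
  normalized cross-correlation, cluster detection (thresholded local maxima),
  11-pixel center-normalized line-scan tension profiles pooled by distance,
  maximal local tension surge within 325 nm (5 px at 65 nm/px), baseline
  back-tracing into pre-treatment coordinates, and a Mann–Whitney U test with
  exact small-sample p-values.
- **`memfluct.coloc`** — object-based colocalization: local-mean thresholding
  with a sensitivity factor, single-pixel despeckling (erosion + dilation
  with a 3×3 cross), cortical-object removal by an area cap, 8-connected
  labeling, summed per-slice colocalized-object fractions and Manders
  coefficients.
- **`memfluct.saxsfcs`** — iteratively-windowed Guinier fits (globular and
  rod), persistence length L = √(12(Rg²−Rc²)) and aspect ratio A = Rg/Rc,
  dimensionless Kratky transform, interparticle-effect detection, the 3-D
  Gaussian one-component FCS model with optional triplet term, beam-waist
  calibration τ_D = ω²/4D, cube-root oligomer counting and a particle-number
  association trend test.
- **`memfluct.reporting`** — nuclear:cytoplasmic intensity ratios
  (cytoplasmic ROI = cell ROI − nuclear ROI), qPCR relative expression
  (2^−ΔCT × 100,000, averaged after transform), YAML config loading and
  deterministic result export with run metadata.

## Command line

All functionality is exposed through the `memfluct` entry point:

```bash
memfluct simulate --preset tirf-irm --seed 1 --out run/     # synthetic movie
memfluct irm-fit  run/movie.tif --out run/fits.csv          # per-region fits
memfluct irm-map  run/movie.tif --out run/map.tif           # pixel-wise map
memfluct correlate run/map.tif run/tirf.tif --out run/profiles.csv
memfluct simulate --preset coloc --seed 2 --out run/
memfluct coloc    run/stack.tif --out run/coloc.csv
memfluct simulate --preset saxs --seed 3 --out run/
memfluct saxs     run/profile.csv --mode globular --out run/guinier.json
memfluct simulate --preset fcs --seed 4 --out run/
memfluct fcs      run/curve.csv --reference-taud 3.6e-5 --out run/fcs.json
memfluct report   --ct-target 25,26,24 --ct-housekeeping 20,20,20 --out run/
```

Movie presets: `tirf-irm` (2,048 frames at 20 Hz, 65 nm pixels) and
`irm-global` (8,192 frames at 50 Hz, 300 nm pixels). Movies are multi-page
TIFF (float32 height / uint16 intensity) with JSON sidecars; curves and
tables are plain CSV.

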