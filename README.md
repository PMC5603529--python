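# endoph

Quantitative analysis of **ratiometric endosomal pH imaging** with
dual-fluorophore biosensors (the SRpHi probe family), built for confocal and
STED (stimulated emission depletion) microscopy data.

Endosomes acidify as they mature, from ~pH 7.4 in nascent vesicles to below
pH 5 in lysosomes. A ratiometric pH probe pairs an acid-quenched fluorescent
protein (FP; EYFP, EGFP or sepHluorin) with an acid-stable organic dye
(Abberior STAR400/410/512), so the FP/dye intensity ratio — not absolute
brightness — reports pH, independent of probe amount and endosome size.
`endoph` implements the full analysis chain for such data, together with a
ground-truthed synthetic-image generator used to validate every stage:

- **photophysics** — single-site protonation (Henderson–Hasselbalch) model of
  FP quenching, `B(pH) = floor + (1-floor)/(1 + 10^(pKa - pH))`, sensor
  ratios and dynamic ranges; built-in registry for SRpHi1–4 (pKa 6.9 / 5.9 /
  7.1 / 6.9).
- **synthetic** — two-channel scene rendering: endosome disks, pH-dependent
  channel brightness, Gaussian PSF (250 nm confocal / 50 nm STED), FP→dye
  spectral bleed-through, Poisson + read noise, 8/16-bit quantization, with
  full ground truth.
- **segmentation** — Otsu threshold (256-bin histogram), 8-connected
  components, ≥5-pixel minimum size, per-region channel means, random-ROI
  background statistics, line-profile FWHM measurement.
- **ratiometry** — per-endosome `log10(FP/dye)`, OLS calibration
  `log10(R) = a·pH + b` on per-pH means, inversion to pH, empirical dynamic
  range `10^(a·ΔpH)`.
- **phmap** — per-pixel 32-bit pH images over the endosome mask, 8-bit linear
  LUT display rescaled over the calibration range, per-endosome pH tables.
- **colocalization** — directional centre-of-mass nearest-neighbour matching
  with threshold = mean equivalent-disk diameter; pooled two-tailed Student's
  t-test for pulse/chase comparisons.
- **pipeline / CLI** — end-to-end workflows with JSON configs, provenance
  records and deterministic seeding; `endoph` console command with
  `simulate-calibration`, `simulate-coloc`, `segment`, `calibrate`, `phmap`,
  `coloc`, `compare` and `fwhm` subcommands.

## Worked example

Simulate a nigericin-style pH-clamped calibration series for SRpHi1
(150 endosomes at each of pH 5.0–7.0 in 0.5 steps, STED optics, realistic
photon noise), segment on the acid-stable dye channel, and fit the standard
curve:

```python
from endoph import RunConfig, run_calibration_workflow

cfg = RunConfig(sensor="SRpHi1", optics="sted", seed=1, n_per_ph=150)
curve, report = run_calibration_workflow(cfg)
print(f"slope {curve.slope:.3f}, R^2 {curve.r_squared:.3f}, "
      f"dynamic range {report['dynamic_range']:.1f}-fold")
print(curve.per_ph[["pH", "mean_log_ratio", "sd_log_ratio", "n"]]
      .round(3).to_string(index=False))
```

prints

```
slope 0.750, R^2 0.995, dynamic range 31.6-fold
 pH  mean_log_ratio  sd_log_ratio   n
5.0          -1.382         0.025 149
5.5          -0.996         0.016 149
6.0          -0.570         0.009 150
6.5          -0.188         0.012 150
7.0           0.089         0.013 150
```

The slope is the calibration gain in log10-ratio per pH unit; R² ≥ 0.99 on
the five per-pH means reproduces the linearity this method is known for, and
the fold change follows as `10^(slope·ΔpH)`. Inverting the curve on new
images (`build_ph_map`, `per_endosome_ph`) converts measured ratios into
per-endosome pH values, e.g. for pulse-chase acidification comparisons.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's headline numbers from scratch: the EYFP-model
residual brightness at pH 5 vs 7, the SRpHi2/SRpHi3 model dynamic ranges,
the apparent FWHM of a 40-nm endosome under confocal and STED PSFs, and the
recovered colocalization percentage for a synthetic punctum pair with a 35%
ground-truth colocalized fraction. All quantities are computed at run time
by the same library code exercised in the test suite.

See `docs/methods.md` for the model assumptions, the synthetic-data world
and its deliberate simplifications, and numerical design choices.
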