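# Methods

## Photophysical model

The acid-sensitive fluorescent protein (FP) channel is modelled by
single-site protonation (Henderson–Hasselbalch form):

    B(pH) = floor + (1 − floor) · 1 / (1 + 10^(pKa − pH))

with `floor` (default 0) the residual brightness at very low pH. At
`pH = pKa` and `floor = 0` the response is exactly 0.5. This functional form
was chosen because, with the registry pKa values (EYFP 6.9, EGFP 5.9,
sepHluorin 7.1), it reproduces the known spectroscopic quenching figures:
EYFP retains 2.23% of its pH-7 brightness at pH 5 ("~2%"), and the derived
sensor dynamic ranges (SRpHi1 44.8-fold over pH 7→5; SRpHi2 20.9-fold over
6.5→4.5; SRpHi3 29.2-fold over 7.5→5.5) exceed the fold changes observed in
cells, as expected when backgrounds and acquisition compromises compress the
measured range.

Dyes are modelled as pH-constant. Their true pKa values are not known; the
dyes are selected for acid stability and any residual response is below what
the analysis can resolve. A log-linear option
(`B = min(1, 10^(slope·(pH − ref_pH)))`) is provided for dyes with a
measured mild attenuation — the registry ships a STAR410 variant with
slope 0.2159 (= −log10(0.37)/2), reproducing a 37% residual at pH 5 vs 7 —
but it is not used by the default sensors.

The sensor ratio is `FP(pH)/dye(pH)`; spectral bleed-through (default 5%,
always <10%) is an imaging effect applied only when rendering the dye
channel, not part of the idealised photophysics.

## Synthetic imaging world

The generator emulates two-channel micrographs of probe-loaded endosomes.
Its defaults are a single, fixed "stated world" chosen once from the imaging
regime the analysis targets; they are not tuned per experiment:

- **Geometry.** Endosomes are uniform 2-D disks, diameters uniform in
  100–400 nm, placed uniformly with a minimum pairwise separation (default
  800 nm) by rejection sampling; infeasible packings fail explicitly.
- **Channel brightness.** Disk amplitude × per-channel gain × relative
  brightness at the endosome's true pH, referenced to pH 7.4 (the
  near-neutral state in which probes are internalised).
- **Optics.** Isotropic 2-D Gaussian PSF parameterised by FWHM
  (σ = FWHM/2.355): confocal 250 nm at 50 nm/pixel, STED 50 nm at
  20 nm/pixel. Disks are rasterised with 4×4 sub-pixel area coverage.
- **Noise and quantization.** Expected counts = photon_scale·signal +
  background; Poisson photon noise, additive Gaussian read noise
  (σ = 2 counts), round-half-up quantization and clipping to 8/16-bit.
  More than 50% saturated pixels aborts the render.
- **Intensity scale.** Dye-channel background 18 counts and default
  amplitude 170 were fixed so that Otsu-segmented dye-channel region means
  sit near 161 counts — the ~9-fold endosome-to-background contrast this
  imaging regime produces. The FP channel uses a lower background
  (2 counts) and a 2× effective gain, reflecting the separate excitation
  line and the deliberately attenuated dye-channel laser power typical of
  these acquisitions. With these defaults and *no background subtraction*
  the full pipeline reproduces the published behaviour of all three probes
  (SRpHi1 noise-free R² ≈ 0.996; SRpHi2 ≈ 17–19-fold over 6.5–4.5;
  SRpHi3 ≈ 24–26-fold over 7.5–5.5).

What the generator does **not** emulate: 3-D structure and defocus,
endosome motion, photobleaching, vesicle substructure, spatially varying
background, detector fixed-pattern noise. A green test therefore
establishes correctness of the analysis under the stated statistical
structure, not robustness to every artefact of real acquisitions.

## Segmentation

Masking runs on the acid-stable dye channel by default (it keeps endosomes
visible at every pH). The Otsu threshold is computed on a 256-bin histogram
(also for 16-bit data) and implemented directly: the returned value is the
class-boundary bin edge, so the inclusive mask `image ≥ threshold` realises
the optimal two-class partition (library implementations return a value
inside the lower class, which breaks inclusive masking on two-valued
images). Components are 8-connected; objects under 5 pixels are discarded —
adopted for *all* analyses to keep region tables consistent. Equivalent-disk
diameter is `2·√(area/π)`.

FWHM measurement extracts the brighter of the x/y line profiles through a
punctum centroid (window 6× the expected FWHM), subtracts the median of the
outer 20% of the window as local background, and locates half-maximum
crossings by linear interpolation. Profiles that never fall below half
maximum (unresolved/overlapping objects) raise an error rather than return
a number. Grid-phase sensitivity is about ±1 pixel: a 40-nm disk under the
250-nm confocal PSF measures 251–263 nm depending on sub-pixel placement
(fine-grid convolution oracle: 251.1 nm), and 56–60 nm under the 50-nm STED
PSF (oracle: 55.9 nm).

## Calibration and pH maps

Per-endosome ratios are `log10(mean_FP/mean_dye)` over exactly the labelled
pixels; no background subtraction is applied before ratioing (available as
an off-by-default option). The calibration is ordinary least squares of the
per-pH *mean* log-ratio against pH, with R² reported on those means — the
statistic quoted for such standard curves — and per-endosome scatter kept
separately as per-pH SD/SEM. Inversion is `(log10 R − b)/a`; estimates
outside the fitted pH range are returned but flagged, since ratio variance
grows quickly outside each probe's usable range (SRpHi1/4: 5.0–7.0,
SRpHi2: 4.5–6.5, SRpHi3: 5.5–7.5).

The protonation model is not exactly log-linear: over pH 5–7 with pKa 6.9
the five-point fit has R² = 0.9912 and linearization residuals up to
0.089 pH at the range ends. Noise-free round-trip accuracy is therefore
bounded by that curvature, not by noise.

Per-pixel pH maps invert the calibration on `log10(FP_px/dye_px)` within the
mask. Pixels with zero counts in either channel, or saturated in either
channel, are excluded and counted; the 8-bit display image maps the
calibration pH range linearly onto 0–255 (0 codes background). Per-endosome
pH is reported both as the mean of pixel pH values and as the pH of the
ratio of means; the two agree exactly only for uniform-ratio regions, so
both are emitted.

## Colocalization

Matching is directional (channel 1 → channel 2), many-to-one, by
centre-of-mass Euclidean nearest neighbour; a pair colocalizes when the
distance is *strictly* less than the threshold, defaulting to the mean
equivalent-disk diameter of the query channel (the channel whose biology is
being asked about). Condition comparisons use the pooled-variance two-tailed
Student's t-test (not Welch), matching the field's standard reporting;
identical degenerate groups are assigned p = 1.

## Statistics conventions

- Population comparisons report mean, SD and SEM (both dispersion measures
  are emitted, labelled, since conventions differ between methods sections
  and figure captions), a pooled two-tailed t-test, and pH histograms in
  0.5-unit bins anchored at integer pH, left-closed right-open.
- Size–intensity regression (area vs mean intensity) is OLS; a constant
  intensity vector returns R² = 0 by convention.
- Calibration workflows warn (not fail) below 150 endosomes per pH value.

## Determinism

All randomness flows from integer seeds through `numpy.random.default_rng`;
series simulations derive per-pH scene and render seeds via
`SeedSequence.spawn`. Identical configs reproduce bit-identical images and
byte-identical CSV/JSON outputs; workflows write a provenance record
(config + library versions).

## Known limitations

- 2-D only; no time-lapse tracking of individual endosomes across frames.
- No watershed splitting of touching endosomes; dense fields undercount.
- Single scalar bleed-through; no wavelength-resolved spectra or unmixing.
- The calibration is linear by design; strongly curved responses (pH ranges
  spanning the pKa by ≫1 unit) should narrow the range instead.
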