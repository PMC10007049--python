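# Methods

## Instrument model

The virtual meter reproduces the measurement chain of a clip-style
dual-wavelength transmittance chlorophyll meter. Two LEDs — red with peak
near 650 nm, near-infrared near 940 nm — illuminate the sample in turn; a
light-to-voltage converter on the opposite side outputs a voltage
proportional to the transmitted intensity. The simulation is band-scalar:
each sample is characterised by one transmittance per band, and the
detector voltage for band *b* is

    V_b = drive_b · responsivity_b · T_b + drift_b

with `drive_b ∈ [0, 1]` the LED drive fraction and `responsivity_b` the
voltage a fully driven LED produces through air. No spectral convolution of
LED emission with detector response is performed; the band-scalar
abstraction is exact for the log-ratio index the device computes, and it
keeps every downstream expectation in closed form.

Each reading passes through an ADC model: additive Gaussian read noise
(SD `read_noise_sd`, default 0.02 V), clamping to `[0, 5 V]`, and uniform
quantization (default 10 bits over a 5 V reference, the native resolution
of the 8-bit AVR microcontroller class such devices use). A scan samples
each band `burst_length = 10` times and averages; the 10 µs inter-sample
spacing of the physical firmware has no simulated effect and is kept as
metadata only, so the burst is modelled as i.i.d. reads.

### Zero calibration

Before any sample scan the meter is zeroed with the clip empty: the drive
of each LED is adjusted until the air voltage equals the calibration target
of 4.6 V — deliberately below the 5 V detector saturation so the
unattenuated path never clips. The physical device does this with manual
multiturn potentiometers; the simulation solves for the drive by bisection
on [0, 1] (≤ 60 iterations, voltage tolerance 0.005 V) and raises a
calibration failure naming the band if the target is unreachable at full
drive. The achieved air voltages are passed through the same ADC
quantizer as sample reads before being persisted. This detail matters: a
noise-free air scan then reproduces the stored reference bit-exactly, so
the air identity (T = 1 in both bands, CCI = 1, M = 0, exactly) holds
despite quantization.

### Index computation and rounding

The device output is the decadic log ratio `M = log10(T_ir/T_red)`; the
base is fixed, not configurable. Internal arithmetic is unrounded;
displayed and logged values are rounded to two decimals, and converted
SPAD/atLeaf estimates to one decimal, matching the three-digit displays of
the commercial meters. Averaged voltages below one ADC step are floored to
half a step before ratio-taking and the result flagged `underflow`, so
near-opaque samples give a finite, flagged index instead of log(0).
Transmittances slightly above 1 (noisy air-like samples) are allowed and
flagged `over_unity`.

## Synthetic samples

**Leaves** follow a per-band decadic Beer–Lambert law. Chlorophyll
contributes absorbance only in the red band (its NIR extinction is
negligible — that is why the NIR band serves as the path-length reference):

    T_red = 10^-(A0_red + eps_red · chl)        T_nir = 10^-(A0_nir)

Defaults: specific red absorbance `eps_red = 1` per chlorophyll unit (this
fixes the scale of the dimensionless `chl_index`), red structural baseline
0.01, NIR baseline 0.30 decades (leaves transmit roughly half the incident
NIR). With these, `M = chl − 0.29` exactly, so the default wide
chlorophyll range (0, 1.21) maps onto device outputs −0.29…0.92, the span
a mixed premature-to-dry leaf panel produces. The `young` stage profile
draws from the central third of the range, emulating a same-age cohort
with its narrower output spread. Leaf area heterogeneity is Gaussian on
`chl` (SD 0.02, floored at 0). The model deliberately omits radiative
transfer, adaxial/abaxial asymmetry, veins, chloroplast movement,
scattering and sieve effects; simulated data are therefore a clean affine
world, and passing tests demonstrate the correctness of the pipeline, not
field performance on real leaves.

**Colour filters** are near-uniform transmittance pairs (per-position
Gaussian jitter, SD 0.004). The `green9` panel places nine filters at
device outputs evenly spread over 0.02…0.82 with NIR transmittance 0.70 —
green gels pass more NIR than red, so all outputs are positive. The
`all13` panel adds four blue filters at the low end (down to −0.09, making
the full-panel output range match the printed filter-experiment span), one
of them a dark-blue outlier. The outlier is implemented as a
reference-reading bias (−6 atLeaf units) rather than a transmittance pair:
emulated reference readings are generated from the device index by an
affine map, so only a bias term can place a filter off the common trend —
physically, it stands for a spectrum that interacts differently with a
reference meter's slightly different LED bands.

**Paired readings.** The reference meters (SPAD-502-like, atLeaf-like) are
emulated by inverting the calibration direction: a conversion model with
known coefficients generates reference readings from the noise-free index
of each measured area, plus Gaussian noise of SD 3.0 target units per
repeat. This single noise term covers both the reference meters' own
dispersion and the spot mismatch of re-clipping three instruments on
approximately the same position; 3.0 units was chosen so that
repeat-averaged residuals land near 0.02–0.04 device units, the magnitude
the field campaigns report, giving simulated R² in the 0.95–0.99 regime.
Because generation is affine with known ground truth, fitted coefficients
are directly checkable.

## Calibration statistics

Pairwise linearity is screened with the 2×2 Pearson correlation matrix
(sample, n−1 covariance). Calibration is ordinary least squares of
reference readings on device output — the same direction as the published
conversion equations, never the reverse — after averaging the 5 repeats
per area (fixed pipeline order). Reported alongside slope and intercept:
R², RMSE in the population convention `sqrt(SSE/n)` (both conventions are
computed; `residual_norm = sqrt(n)·RMSE` is asserted in tests), and a
t-based two-sided 95 % band. The band is a *prediction* interval for a
new observation, `ŷ ± t_{0.975,n−2}·s·sqrt(1 + 1/n + (x0−x̄)²/Sxx)` — the
stricter of the two readings of "confidence prediction intervals", and the
one consistent with the claim that a new measurement falls within the
bands with 95 % probability.

Regression points are per-area averages pooled across samples (e.g. 30
leaves × 5 areas → 150 points) rather than one average per leaf; the
repeat-averaging helper leaves this configurable by what the caller
passes.

The six built-in conversion presets (lemon/sprouts/non-leaves ×
SPAD/atLeaf) have positive slopes; conversion applies `slope·M +
intercept` with a one-decimal display form, and inversion is the exact
affine inverse, so a convert–invert round trip is an identity up to one
display-rounding step.

## Accuracy and repeatability protocol

Evaluation runs on uniform filter-style datasets (default 10 positions × 5
repeats per dataset), in device units, with unit conversion applied last:

- **accuracy range** — per dataset, deviations of the 5-repeat position
  averages from the dataset's own mean; the global minimum and maximum
  across datasets. Deviations from an own mean sum to zero, so the range
  always straddles 0.
- **repeatability** — the pooled SD, `sqrt(mean over positions of the
  per-position sample variance)`, the metrologically standard summary of
  same-position dispersion. The mean of per-position SDs is available as
  an alternative (`method="mean_sd"`), since the protocol's verbal
  definition admits both readings.

Re-expressing a device-unit report in SPAD or atLeaf units multiplies
spread quantities by the conversion slope only; intercepts cancel in
differences and SDs, avoiding double rounding.

## Log format

Each measurement is one CSV row: number, ISO-8601 timestamp, both air
voltages, both transmittances, M, optional SPAD/atLeaf estimates, optional
GPS coordinates (signed decimal degrees), and a checksum — CRC-32 of the
comma-joined preceding fields as eight lowercase hex digits. The physical
device specifies a checksum but not its construction; CRC-32 is a
documented artifact convention, cheap on microcontroller-class hardware
and guaranteed to catch any single-character (≤ 8-bit burst) corruption,
which the fuzz tests confirm over 10³ mutations. Stored values carry
display precision, making write→read→write byte-stable. Session
operations mirror the firmware menu: append (strictly increasing
numbering), reject-last (no renumbering), and field averaging over
records where the field is present.

## Numerical and testing choices

- All stochastic code takes an explicit `numpy.random.Generator`; there is
  no global RNG state, and fixed seeds give bit-identical panels, tables
  and scan results.
- OLS, Pearson and the prediction band are cross-checked in the test suite
  against an independent normal-equations solve, direct evaluation of the
  correlation formula, and statsmodels' prediction frame, to 1e−9.
- Monte-Carlo checks use fixed seeds and modest sizes: 2000 replicates for
  95 % prediction-interval coverage (tolerance ±1.5 points), 500
  replicates for slope-CI coverage (≥ 93 %), 90 points × 5 repeats for
  repeatability recovery (±15 %).
- Simulated campaigns use the field designs as-is (30×5×5, 32×3×5,
  9×10×5); each runs in seconds.

## Known limitations

- Band-scalar optics: no spectral resolution, so effects that depend on
  band *shape* (LED spectral width, detector response slope across the
  band) are outside the model.
- The conversion presets are instrument- and species-specific empirical
  fits; nothing here relates device output to absolute chlorophyll
  concentration, which requires destructive chemistry-based calibration.
- The reference-meter emulation is affine-by-construction; it cannot probe
  nonlinearity between real meters at extreme readings.
- Temperature drift of the LED drive is exposed only as a static per-band
  voltage offset (default 0), not as a time-dependent process.
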