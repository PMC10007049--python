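# virtuchlor

A virtual dual-wavelength transmittance chlorophyll meter.

Hand-held chlorophyll meters (SPAD-502, atLeaf CHL Plus, CCM-200 and kin)
estimate relative leaf chlorophyll non-destructively by shining two LEDs —
red (~650 nm, where chlorophyll absorbs strongly) and near-infrared
(~940 nm, a reference band where it does not) — through a clipped leaf and
comparing the transmitted intensities against stored "air" (empty clip)
references. `virtuchlor` is a software twin of a low-cost meter of this
class, for instrument developers, plant-phenotyping methodologists and
teachers who want the full measurement chain — LED drive, light-to-voltage
detection, zero calibration, ADC quantization and noise, burst averaging,
display rounding, SD-card-style logging — available, reproducible and
testable without hardware.

## The measurement model

With per-band percentage transmittances `T_red = V_red / V_red,air` and
`T_ir = V_ir / V_ir,air`, the meter computes

- the chlorophyll content index `CCI = T_ir / T_red` (the simple-ratio
  convention), and
- the device output `M = log10(T_ir / T_red)`, the decadic log ratio that
  SPAD-type meters gain and offset as `k·log10(CCI) + C` (the
  manufacturers' k and C are proprietary).

Because every meter in this family reads an affine transform of the same
log ratio, cross-instrument calibration is ordinary least squares of the
reference meter's readings on `M`, and the fitted line doubles as the unit
conversion `V_target = slope·M + intercept`. The package carries the
published conversion presets for three sample families (lemon-tree leaves,
young Brussels-sprouts leaves, and uniform colour filters), and implements
the accompanying evaluation protocol: accuracy as the global min/max
deviation of position averages from each dataset's own mean, and
repeatability as the pooled standard deviation of repeated readings at a
fixed position.

Synthetic samples come from a decadic Beer–Lambert leaf model (chlorophyll
absorbs only in the red band; NIR sees the structural baseline) and from
near-uniform colour-filter models, with the field sampling designs built
in (30 leaves × 5 areas × 5 repeats; 32 leaves × 3 areas × 5 repeats;
9–13 filters × 10 positions × 5 repeats).

## Worked example

```sh
$ virtuchlor simulate --preset green9 --seed 5 --out readings.csv
wrote 450 readings to readings.csv

$ virtuchlor calibrate --readings readings.csv --y spad
spad = 63.133 x M + 13.168   R2=0.9924  RMSE=1.4261  n=90

$ virtuchlor evaluate --readings readings.csv --units spad --conversion nonleaves
accuracy [-1.7582, +1.6424] spad units; repeatability 0.2096

$ virtuchlor convert --model lemon_spad --value 0.0
13.5 spad units (exact 13.5470)
```

The simulated nine-green-filter campaign (5 repeats at each of 10 positions
per filter, repeat-averaged before fitting) yields a cross-meter line with
R² ≈ 0.992: slope and intercept land near the generating non-leaves preset
(62.893, 13.27), the difference being instrument and position noise. The
evaluation line says simulated position averages deviated at most about
−1.8/+1.6 SPAD units from their filter means, with a pooled repeat SD of
0.21 SPAD units. Converting a device reading of 0 with the lemon-tree
preset returns the intercept, displayed at the meters' one-decimal
precision.

In Python the same pipeline is:

```python
import numpy as np
from virtuchlor import (Instrument, zero_calibrate, make_filter_panel,
                        SamplingDesign, simulate_paired_readings,
                        get_preset, fit_linear)
from virtuchlor.calibration_stats import average_repeats

rng = np.random.default_rng(5)
inst = Instrument()
air = zero_calibrate(inst)                      # air reads 4.60 V per band
panel = make_filter_panel("green9")
design = SamplingDesign(n_samples=9, areas_per_sample=10)
convs = [get_preset("nonleaves", t) for t in ("spad", "atleaf")]
table = simulate_paired_readings(panel, design, inst, air, convs, rng)
avg = average_repeats(table)
fit = fit_linear(avg["M"], avg["spad"])
print(fit.slope, fit.intercept, fit.r2)
```

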