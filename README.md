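# ringprofiler

Quantification of ring-patterned microcapillary networks in fluorescence
microscopy images.

Acoustic (Faraday-wave) cell patterning can condense an endothelial-cell
suspension into a reproducible annular condensate that self-assembles into a
ring-shaped microcapillary network inside a hydrogel. Because the pattern is
radially symmetric, its entire morphology can be read out from 2-D
fluorescence projections with a single 1-D statistic. This package implements
that workflow end to end for experimentalists running such assays (and for
anyone validating radial-profile image quantification): synthetic
ground-truth image generation, Z-stack projection, the radial profile and its
readouts, ring-continuity indices, binary-mask network-area tracking over
days, and control-referenced group statistics.

## The statistic

For a frame `I(x, y)` with center `c`, the **radial profile** aggregates
intensity over circles of radius `r`:

    P(r) = agg { I(p) : |p − c| ∈ [r, r + Δr) },   r swept over 360°,

with `agg` either the per-bin sum or mean. For a ring-shaped network:

- **radius** — the position of the profile's peak (reported as diameter
  `D = 2 r_peak`);
- **thickness** — the full width at half maximum (FWHM) of the peak, with the
  half level referenced to the estimated background pedestal;
- **AUC** — the trapezoidal integral `∫ P(r) dr`, a proxy for total network
  abundance, compared across days as a ratio to a baseline day;
- **peak intensity** (sum aggregation) — proportional, at fixed geometry and
  amplitude, to the fraction of the circle the ring covers, i.e. a
  **continuity** readout. An independent angular-occupancy index (fraction of
  1° sectors of the measured annulus carrying signal) validates it.

Network growth is tracked separately: frames are thresholded (Otsu, locked to
the baseline day across a series), speckles below 100 µm² removed, and total
foreground area reported as percent of the day −1 area.

A peak counts as *characteristic* of a ring only if it is prominent over the
profile pedestal (≥ 0.6 of the peak), wide enough to be a cell condensate
(≥ 150 µm at half prominence), and a true annulus (radius ≥ width).
Homogeneously seeded control networks fail these tests and yield an explicit
no-peak record.

## Worked example

```python
from ringprofiler import (SyntheticRingSpec, NoiseSpec, DynamicsSpec,
                          generate_ring_image, generate_timecourse,
                          measure_ring, relative_growth)
from ringprofiler.networkarea import binarize_series

# one study-like image: 3.58 mm field, ring 1781 µm diameter / 416 µm FWHM
spec = SyntheticRingSpec(seed=42)
frame, truth = generate_ring_image(spec, NoiseSpec(seed=42))
m = measure_ring(frame)
print(m.diameter_um, m.thickness_um, m.continuity_index)

# a six-day growth series programmed to peak at 145% of baseline on day 2
days = list(DynamicsSpec().days)
frames, _ = generate_timecourse(
    SyntheticRingSpec(image_size_px=(448, 448), microns_per_pixel=8.0, seed=42),
    NoiseSpec(seed=43), DynamicsSpec())
tc = relative_growth(binarize_series(frames, days), days)
print(tc.table)
```

prints (abridged):

```
diameter  :  1779.8 um   (true 1781)
thickness :   437.3 um   (true 416)
continuity:    1.00
 day  total_area_um2  relative_growth_percent
  -1       2937984.0               100.000000
   0       3240384.0               110.292772
   1       3762624.0               128.068226
   2       4236416.0               144.194659
   3       3543744.0               120.618220
   4       2911168.0                99.087265
```

The measured diameter lands within 0.1% of the generating truth; thickness is
within 5% (the filament background under the crest adds a small positive
bias, absent on pre-network images); the programmed ×1.45 day-2 growth is
read back as 144.2%.

The same stages are scriptable from a shell:

```bash
ringprofiler simulate timecourse --out sim/ --seed 1
ringprofiler measure sim/day*.tif --microns-per-pixel 4 --out rings.csv
ringprofiler track sim/day*.tif --days -1,0,1,2,3,4 --microns-per-pixel 4 --out area.csv
ringprofiler compare observations.csv --control EGM2 --out stats.json
ringprofiler run --config study.toml --seed 1   # full bundle + manifest
```

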