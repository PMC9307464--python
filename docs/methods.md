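# Methods

This note documents the models implemented in `ringprofiler`, the defaults
and why they were chosen, and the numerical decisions made where the design
was genuinely open. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## The imaging scenario

The package targets single-channel fluorescence images of sound-patterned
endothelial cultures: a bright annular cell condensate (the patterned ring)
over a dimmer background of self-assembled capillary filaments, acquired as
tiled confocal Z-stacks and analysed on 2-D maximum-intensity projections.
The default physical scale is a 3.58 mm × 3.58 mm field imaged as 225 µm
stacks at 17.3 µm slice spacing; the nominal ring is 1781 µm in diameter
with a 416 µm thick cross-section, and between-pattern variability is
SD 142 µm (diameter) and 124 µm (thickness). Tile stitching, flat-field
correction, registration and deconvolution are out of scope; inputs are
assumed stitched and single-channel (multi-channel files require an explicit
channel index).

One bookkeeping caveat: the nominal scanned area of that acquisition is
quoted as 13.8 mm², which is not the square of the 3.58 mm field edge
(12.8 mm²). `imaged_region_geometry` therefore accepts a directly supplied
area — instruments report nominal scan areas that need not equal the pixel
grid product — and volume is always area × axial depth (13.8 mm² × 225 µm
= 3.1 mm³).

## Synthetic image model

The generator is first-class, deterministic code; every downstream stage is
validated against it.

**Ring.** The annular condensate is Gaussian in radius:
`A_ring · exp(−(r − R)² / 2σ²)` with `σ = thickness / 2.3548`, so "thickness"
is by construction the FWHM that the profile readout recovers. Continuity is
modelled by an angular indicator covering `arc_fraction` of the circle; the
default gap layout is a single contiguous gap at a seeded-uniform start
angle (the simplest monotonicity probe), with explicit `(start, end)`
layouts available.

**Filaments.** Capillaries are smoothed random-walk polylines (12 steps of
50 µm, heading jitter SD 0.35 rad) splatted at fixed arc-length spacing and
blurred to a Gaussian transverse profile of FWHM `branch_width_um` (default
30 µm). Their brightness (`background_amplitude`, default 8000 AU against a
ring amplitude of 10000 AU) makes the filament class clearly super-threshold
for any sensible global binarisation, as it must be for area tracking to see
the network at all; branching statistics are free parameters, not claims
about real capillaries.

**Ground truth is bookkeeping, never re-measurement.** The true foreground
is the half-maximum set of each noiseless component field; for the ring
alone this area is ≈ π · D · t · arc_fraction, and the annulus crest sits at
exactly `D/2`. Rendering the same scene at twice the resolution changes the
bookkept area by < 2% (asserted in tests).

**Noise.** The source micrographs are not noise-characterised, so the model
is generic confocal noise with defaults chosen for plausibility, flagged as
unvalidated against real data: Gaussian read noise (σ = 300 AU), Poisson
shot noise (0.02 expected counts per AU), and a linear shading gradient
(10% across the field along a seeded random direction). Intensities are
arbitrary units in [0, 65535]; frames are written as 16-bit TIFF.

**Timecourses.** `DynamicsSpec` maps day labels to target area multipliers
(vs day −1), thickness multipliers and arc fractions. The default growth
trajectory rises to ×1.45 on day 2 and returns to ×0.98 on day 4;
`regression_dynamics()` gives the no-stimulus counterpart (retraction to
baseline with continuity loss). The filament skeleton is fixed across days
— vessels thicken or thin in place — and the branch width is solved per day
by bisection so the bookkept area hits the target within 1%. Targets below
the ring's own area or beyond ×40 branch growth raise a geometry error.

**Replicates.** Per-replicate diameters/thicknesses are drawn from normal
laws truncated to valid geometry (rejection sampling; a law with essentially
no valid mass raises). Seeds spawn via `SeedSequence`, so replicate sets are
reproducible element-wise.

**Random-network controls.** The unpatterned control condition carries the
same cell mass as a patterned well, spread homogeneously. Equating total
fluorescence mass (ring area × ring amplitude ≈ n × filament area ×
filament amplitude) gives ≈ 160 filaments for the default scene, against
40 peripheral filaments in ring images; discrimination tests use this
mass-matched control. A 40-filament "random" field is not homogeneous — its
density fluctuations are themselves ring-sized structures.

## Center estimation

`intensity_centroid` (default) is exact for full rings but biased toward the
arc for broken ones (≈ 40–55 px for a half ring at 8 µm/px). `grid_refined`
recovers the true center in two stages:

1. **Coarse descent** on the *radial concentration* objective — the
   intensity captured by the best single radial bin of the sum-aggregated
   profile (2-px bins, hill-climb from step = image/8 down to 2 px). Only
   the true circle center places the whole arc at one radius. Normalised
   objectives (peak/FWHM on the mean profile) were tried and rejected: they
   develop spurious optima, because narrow bright bumps score arbitrarily
   high and, under mean aggregation, centers shifted toward the arc are
   rewarded for pushing the empty gap-side annulus outside the field.
2. **Crest-weighted geometric circle fit.** Pixels within one measured FWHM
   of the peak radius and above 60% of the zone's 99th intensity percentile
   are fit by Gauss–Newton on the radial residuals, weighted by intensity
   (three outer iterations). The algebraic (Kåsa) fit was rejected after
   showing a constant ≈ 8 px bias on half rings; the geometric fit is exact
   there (< 0.05 px on clean half rings, ≲ 3 px with filaments).

A manual center override is first-class (`measure_ring(center=...)`),
mirroring workflows where the ROI is placed by hand.

## Radial profile

Every pixel at distance `d < r_max` contributes exactly once to bin
`⌊d / Δr⌋`; bin width defaults to one pixel, radii are reported at bin
centers, `r_max` defaults to the distance to the nearest image edge. Sums
and counts are kept per bin so sum/mean aggregation are interconvertible
and `Σ n_pixels` is exactly the disk's pixel count. On small images the
implementation is bit-identical to a naive double loop (same accumulation
order), which the suite asserts.

## Peak, FWHM, AUC

`measure_ring` lightly smooths the profile (20 µm moving average — an order
of magnitude below the condensate scale; width inflation for the default
geometry is < 0.1%) so filament texture cannot jitter the argmax.

**Characteristic-peak rule.** The ring peak is the brightest local maximum
(on bins covering ≥ 16 pixels) satisfying all of:

- prominence over the profile's global-median pedestal ≥ 0.6 of the peak;
- width at the half-prominence level ≥ 150 µm;
- radius ≥ width (a true annulus — otherwise the "ring" encloses the
  profile origin, the signature of a center estimate sitting on a bright
  clump).

Candidates are scanned in descending height, so a narrow bright spike skips
to a genuine crest rather than masking it. The thresholds are an operating
point calibrated on generator sweeps: the width floor encodes that a
patterned condensate is an order of magnitude wider than single filaments
(chance clumps measure ≲ 130 µm), and 0.6 sits mid-gap between the largest
qualifying bump seen in dense homogeneous controls (0.56) and the weakest
true-ring case measured (0.68, a quarter ring on a small field). Images
failing the rule produce a no-peak record with absent (never zero-filled)
readouts. Ties at the maximum break toward the smaller radius and are
flagged.

**Radius.** Reported as the midpoint of the two half-maximum crossings
(equal to the peak position for any symmetric cross-section and far more
texture-robust than the argmax); a three-point parabolic refinement of the
argmax is the fallback when a crossing is missing.

**Baseline.** The FWHM pedestal is the median of covered bins whose distance
from the peak lies in one to two peak-widths (initial width from the
zero-baseline crossings). A far-field median underestimates the pedestal
under the crest (filament coverage is itself structured radially), and the
band variant also degrades gracefully on rings that fill the whole field.
The baseline is configurable (`baseline=0.0` reproduces a zero-baseline
convention) and recorded, since the choice shifts thickness on
pedestal-heavy images: on the default network-bearing scene the crossing
width reads ≈ 5% above the generating FWHM, while on pre-network
(patterning-day) images it is exact to three digits.

**One-sided peaks.** If the half level is never crossed on one side
(truncated ring), the width is twice the available half-width and the
record is flagged, not silently dropped.

**AUC** is the trapezoidal integral of the sum-aggregated profile over its
full support. Because acquisition gain is arbitrary, day comparisons use
ratios to a baseline day (`compare_day_series`), with percent changes
reported as (treated/control − 1) × 100.

## Continuity

Two readouts, by design. The *peak-intensity proxy* (sum-aggregated peak
value) is the field's readout: at fixed geometry and amplitude it is exactly
proportional to the arc present — and equally proportional to amplitude,
a confounder the tests document. The *angular-occupancy index* is the
interpretable oracle: the fraction of 360 sectors of the measured annulus
`[D/2 − t/2, D/2 + t/2]` whose mean intensity exceeds a threshold. The
default threshold is Otsu over the whole frame: the frame's background
supplies the reference class. Otsu restricted to annulus pixels (also
available) is only well-posed when gaps actually exist — on an unbroken
ring it splits the signal against itself and misclassifies sectors. Across
arc sweeps the two readouts agree with R² > 0.95, which is the package's
validation of the proxy.

## Network-area tracking

Masks come from a global threshold (Otsu default; fixed level for
sensitivity analysis), followed by removal of objects under 100 µm²
(noise speckle). For longitudinal series, `binarize_series` determines the
threshold once on the baseline day and holds it fixed (`lock_threshold`,
default on): a per-frame auto-threshold drifts with the day's foreground
mass and imprints a spurious compressive trend on growth curves (≈ −13
percentage points at a programmed ×1.45 in development measurements).
Total area is foreground pixel count × (µm/px)²; growth is percent of the
day −1 area (the delta convention, day −1 = 0%, is a switch). Zero baseline
area and constant frames raise explicit errors.

## Group statistics

Per-group mean/SD (n−1) with n < 2 flagged; one-way ANOVA followed by
Dunnett many-to-one comparisons against the control, pooling all
observations (no experiment-level nesting — both pooling modes of the
underlying data can be fed in, and the table records what was used).
Dunnett's adjusted p-values come from the multivariate-t distribution
(scipy's quadrature implementation, seeded); unadjusted per-comparison
p-values use the same pooled-variance t statistic, and adjusted values are
floored at the unadjusted ones so quadrature error can never make
adjustment anti-conservative. An all-identical table is reported as
non-significant by construction rather than as an error. Star tiers follow
the conventional GraphPad-style cutoffs (∗ < 0.0332, ∗∗ < 0.0021,
∗∗∗ < 0.0002, ∗∗∗∗ < 0.0001) as presentation only, decoupled from the
testing alpha. Under a simulated global null (k = 3, n = 3) the family-wise
error rate is ≈ 0.05, asserted ≤ 0.06 over 1000 replicates.

## Pipeline and reproducibility

`run_experiment` executes simulate → project → measure → track → compare
with one `RunConfig`; every tunable and seed lands in `manifest.json`, and
re-running a configuration reproduces the CSV/JSON outputs byte-for-byte
(asserted). Per-image failures (e.g. a corrupt TIFF) are isolated, listed in
the manifest, and do not abort the run. The CLI exposes the same stages
(`simulate`, `measure`, `track`, `compare`, `run`) with exit codes 2/3/4
for configuration, I/O and analysis errors.

## Problem sizes

Full-resolution scenes are 895 px at 4 µm/px (the physical field). Sweeps,
timecourses and discrimination runs use the same physical scene at 8 µm/px
(448 px), a resolution at which all readouts are within their stated
tolerances; single-image recovery checks run at full resolution. The
Dunnett null uses 1000 replicates.

## What passing tests do and do not show

The generator emulates the *statistical shape* of the assay — annular
condensate plus filament background, programmable growth/regression and
continuity loss, replicate variability, generic confocal noise. It does not
emulate uneven illumination beyond a linear ramp, depth-dependent blur,
spectral bleed-through, segmentation-relevant debris, or biological
morphology (anastomoses, sprout directionality). Recovery results here
therefore demonstrate correctness of the measurement chain, not performance
on any particular microscope's data; physical readouts on real images
require the user-supplied pixel calibration, and the FWHM baseline choice
should be revisited on pedestal-heavy data.

## Known limitations

- The thickness readout carries a small positive bias (order 5%) when a
  bright filament network underlies the ring crest; the banded baseline
  reduces but cannot eliminate it.
- The characteristic-peak thresholds (0.6 prominence, 150 µm width) are an
  operating point for condensate-scale rings; assays with much thinner
  patterns need `min_peak_width_um` lowered accordingly.
- `grid_refined` assumes a single ring; concentric or multiple rings are
  out of scope.
- Area tracking quantifies area only — no skeletonisation, branch counts or
  junction metrics.
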