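"""Radial intensity profiles: the core 1-D statistic of the pipeline.

A radial profile aggregates pixel intensity as a function of radial distance
from a chosen center, swept over the full 360 degrees. For a ring-patterned
fluorescent network the profile shows a peak whose position is the ring's
radius, whose full width at half maximum (FWHM) is its thickness, and whose
height and integral (AUC) track continuity and total network abundance.

Binning contract: every pixel at distance d < r_max from the center
contributes exactly once to bin floor(d / bin_width). ``sum`` aggregation
stores per-bin totals; ``mean`` divides by the per-bin pixel count. Radii are
reported at bin centers, in microns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io_imaging import ImageFrame


@dataclass(frozen=True)
class CenterEstimate:
    """A ring-center estimate in pixel coordinates."""

    x_px: float
    y_px: float
    method: str = "provided"


@dataclass
class RadialProfile:
    radii_um: np.ndarray  # bin centers, strictly increasing
    values: np.ndarray  # aggregated intensity per bin
    bin_width_um: float
    aggregation: str  # "sum" | "mean"
    center: CenterEstimate
    n_pixels_per_bin: np.ndarray
    sums: np.ndarray  # per-bin intensity totals (kept for re-aggregation)
    microns_per_pixel: float = 1.0

    def __post_init__(self) -> None:
        if not (len(self.radii_um) == len(self.values) == len(self.n_pixels_per_bin)):
            raise ValueError("profile arrays must have equal length")

    def as_aggregation(self, aggregation: str) -> "RadialProfile":
        """Return the same profile under the other aggregation rule."""
        if aggregation == self.aggregation:
            return self
        if aggregation == "sum":
            values = self.sums.copy()
        elif aggregation == "mean":
            with np.errstate(invalid="ignore", divide="ignore"):
                values = np.where(self.n_pixels_per_bin > 0, self.sums / self.n_pixels_per_bin, 0.0)
        else:
            raise ValueError(f"unknown aggregation {aggregation!r}")
        return replace(self, values=values, aggregation=aggregation)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"radius_um": self.radii_um, "value": self.values, "n_pixels": self.n_pixels_per_bin}
        )


@dataclass(frozen=True)
class PeakResult:
    radius_um: float
    value: float
    index: int
    tie: bool = False
    refined: bool = False


@dataclass(frozen=True)
class FWHMResult:
    width_um: float
    left_um: float | None
    right_um: float | None
    baseline: float
    one_sided: bool = False


def estimate_center(frame: ImageFrame, method: str = "intensity_centroid") -> CenterEstimate:
    """Locate the ring center.

    ``intensity_centroid`` is the intensity-weighted centroid — exact for a
    full ring, biased toward the arc for broken rings. ``grid_refined``
    descends from the centroid on a coarse-to-fine grid, maximising the
    radial concentration of the sum-aggregated profile (the intensity
    captured by the best single radial bin), which recovers the true center
    even for half rings.
    """
    pixels = np.asarray(frame.pixels, dtype=np.float64)
    total = pixels.sum()
    if total <= 0:
        raise ValueError("cannot estimate a center on an all-zero frame")
    h, w = pixels.shape
    y, x = np.mgrid[0:h, 0:w]
    cx = float((pixels * x).sum() / total)
    cy = float((pixels * y).sum() / total)
    if method == "intensity_centroid":
        return CenterEstimate(cx, cy, "intensity_centroid")
    if method != "grid_refined":
        raise ValueError(f"unknown center method {method!r}")

    coarse_bin = 2.0 * frame.microns_per_pixel  # coarse 2-px bins keep the search cheap

    def sharpness(px: float, py: float, bin_um: float) -> float:
        # Radial concentration: the total intensity captured by the single
        # best radial bin. Only the true circle center places the whole arc
        # at one radius, so this is maximised there for full and broken
        # rings alike. (Normalised variants — peak/FWHM on the mean profile —
        # develop spurious optima: narrow bright bumps score arbitrarily
        # high, and centers shifted toward the arc get rewarded for pushing
        # the empty gap-side annulus outside the field.)
        if not (0 <= px < w and 0 <= py < h):
            return -np.inf
        prof = compute_radial_profile(
            frame,
            CenterEstimate(px, py, "provided"),
            bin_width_um=bin_um,
            aggregation="sum",
        )
        peak = profile_peak(prof, min_pixels_per_bin=16)
        if peak is None:
            return -np.inf
        return peak.value

    best = (cx, cy)
    neighbours = ((1, 0), (-1, 0), (0, 1), (0, -1), (1, 1), (1, -1), (-1, 1), (-1, -1))

    def descend(start, start_step, stop_step, bin_um):
        best_pt = start
        best_score = sharpness(*best_pt, bin_um)
        step = start_step
        while step >= stop_step:
            moved = True
            while moved:
                moved = False
                for dx, dy in neighbours:
                    cand = (best_pt[0] + dx * step, best_pt[1] + dy * step)
                    score = sharpness(*cand, bin_um)
                    if score > best_score:
                        best_pt, best_score = cand, score
                        moved = True
            step /= 2.0
        return best_pt

    # coarse descent handles the large centroid bias of broken rings; a
    # crest-weighted circle fit then polishes to (sub-)pixel precision
    best = descend(best, max(h, w) / 8.0, 2.0, coarse_bin)
    best = _kasa_polish(frame, best[0], best[1])
    return CenterEstimate(best[0], best[1], "grid_refined")


def _kasa_polish(
    frame: ImageFrame, cx: float, cy: float, n_iter: int = 3, crest_frac: float = 0.6
) -> tuple[float, float]:
    """Refine a ring center by an intensity-weighted algebraic circle fit.

    Pixels on the annulus crest — within half the measured FWHM of the peak
    radius and above ``crest_frac`` of the local maximum — are fit to a
    circle (Kasa's linear least squares), weighted by intensity. The crest
    selection excludes the dimmer filament background, so the fit follows
    the condensate arc even for broken rings. Falls back to the input center
    when no usable crest is found.
    """
    pixels = np.asarray(frame.pixels, dtype=np.float64)
    h, w = pixels.shape
    mpp = frame.microns_per_pixel
    y, x = np.mgrid[0:h, 0:w]
    for _ in range(n_iter):
        prof = compute_radial_profile(
            frame, CenterEstimate(cx, cy), bin_width_um=2 * mpp, aggregation="sum"
        )
        peak = profile_peak(prof, min_pixels_per_bin=16)
        if peak is None:
            return cx, cy
        r_px = peak.radius_um / mpp
        prof_mean = prof.as_aggregation("mean")
        peak_mean = profile_peak(prof_mean, min_pixels_per_bin=16)
        pedestal = float(np.median(prof_mean.values[prof_mean.n_pixels_per_bin > 0]))
        fw = profile_fwhm(prof_mean, peak_mean, baseline=pedestal)
        # full-FWHM zone so a biased center cannot truncate the crest
        # asymmetrically; percentile reference so bright filament crossings
        # cannot push the crest threshold above the ring's own level
        zone_width_px = (fw.width_um / mpp) if fw is not None else 20.0
        ring_zone = np.abs(np.hypot(x - cx, y - cy) - r_px) < zone_width_px
        if not ring_zone.any():
            return cx, cy
        thr = crest_frac * np.percentile(pixels[ring_zone], 99)
        sel = ring_zone & (pixels > thr)
        if sel.sum() < 20:
            return cx, cy
        xs = x[sel].astype(np.float64)
        ys = y[sel].astype(np.float64)
        wgt = pixels[sel]
        fit = _fit_circle(xs, ys, wgt, cx, cy, r_px)
        if fit is None:
            return cx, cy
        cx, cy = fit
        if not (0 <= cx < w and 0 <= cy < h):
            return cx, cy
    return cx, cy


def _fit_circle(xs, ys, wgt, cx0, cy0, r0, n_iter=10):
    """Weighted geometric circle fit (Gauss-Newton on radial residuals).

    The algebraic (Kasa) fit is biased toward the arc for partial rings;
    minimising the true radial residuals sum w (|p - c| - R)^2 is not.
    """
    cx, cy, r = float(cx0), float(cy0), float(r0)
    for _ in range(n_iter):
        dx = xs - cx
        dy = ys - cy
        d = np.hypot(dx, dy)
        d = np.maximum(d, 1e-9)
        resid = d - r
        # Jacobian of resid wrt (cx, cy, r)
        j = np.stack([-dx / d, -dy / d, -np.ones_like(d)], axis=1)
        jtw = j.T * wgt
        try:
            step = np.linalg.solve(jtw @ j, jtw @ resid)
        except np.linalg.LinAlgError:
            return None
        cx -= step[0]
        cy -= step[1]
        r -= step[2]
        if np.hypot(step[0], step[1]) < 1e-4:
            break
    return cx, cy


def compute_radial_profile(
    frame: ImageFrame,
    center: CenterEstimate,
    r_max_um: float | None = None,
    bin_width_um: float | None = None,
    aggregation: str = "mean",
) -> RadialProfile:
    """Aggregate intensity against radial distance from ``center``.

    ``r_max_um`` defaults to the distance from the center to the nearest
    image edge (all bins fully covered); larger values are allowed, in which
    case partially covered bins are visible through ``n_pixels_per_bin``.
    ``bin_width_um`` defaults to one pixel.
    """
    pixels = np.asarray(frame.pixels, dtype=np.float64)
    h, w = pixels.shape
    mpp = frame.microns_per_pixel
    if not (0 <= center.x_px <= w - 1 and 0 <= center.y_px <= h - 1):
        raise ValueError("center lies outside the image")
    if bin_width_um is None:
        bin_width_um = mpp
    if bin_width_um < mpp:
        raise ValueError("bin width must be at least one pixel")
    if r_max_um is None:
        r_max_um = (
            min(center.x_px, w - 1 - center.x_px, center.y_px, h - 1 - center.y_px) * mpp
        )
    if r_max_um <= 0:
        raise ValueError("r_max_um must be positive")
    if aggregation not in ("sum", "mean"):
        raise ValueError(f"unknown aggregation {aggregation!r}")

    y, x = np.mgrid[0:h, 0:w]
    d_um = np.sqrt((x - center.x_px) ** 2 + (y - center.y_px) ** 2) * mpp
    inside = d_um < r_max_um
    idx = np.floor_divide(d_um[inside], bin_width_um).astype(np.intp)
    n_bins = int(math.ceil(r_max_um / bin_width_um))
    sums = np.bincount(idx, weights=pixels[inside], minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    radii = (np.arange(n_bins) + 0.5) * bin_width_um
    if aggregation == "sum":
        values = sums.copy()
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            values = np.where(counts > 0, sums / counts, 0.0)
    return RadialProfile(
        radii_um=radii,
        values=values,
        bin_width_um=bin_width_um,
        aggregation=aggregation,
        center=center,
        n_pixels_per_bin=counts,
        sums=sums,
        microns_per_pixel=mpp,
    )


def profile_peak(
    profile: RadialProfile,
    refine: bool = False,
    min_pixels_per_bin: int = 0,
) -> PeakResult | None:
    """Global maximum of the profile.

    Returns None (a "no peak" signal, distinct from an error) when the profile
    carries no positive signal. Ties are broken toward the smaller radius and
    flagged. With ``refine``, a three-point parabolic fit sharpens the radius
    to sub-bin precision. ``min_pixels_per_bin`` excludes sparsely covered
    bins (e.g. the innermost ones) from peak eligibility.
    """
    if len(profile.values) == 0:
        raise ValueError("empty profile")
    eligible = profile.n_pixels_per_bin >= min_pixels_per_bin
    if not eligible.any():
        return None
    vals = np.where(eligible, profile.values, -np.inf)
    if np.nanmax(vals) <= 0:
        return None
    i = int(np.argmax(vals))  # argmax returns the first (smallest-radius) max
    vmax = float(vals[i])
    tie = bool(np.count_nonzero(vals == vmax) > 1)
    radius = float(profile.radii_um[i])
    refined = False
    if refine and 0 < i < len(vals) - 1 and np.isfinite(vals[i - 1]) and np.isfinite(vals[i + 1]):
        denom = vals[i - 1] - 2.0 * vals[i] + vals[i + 1]
        if denom < 0:
            shift = 0.5 * (vals[i - 1] - vals[i + 1]) / denom
            if abs(shift) <= 1.0:
                radius = radius + shift * profile.bin_width_um
                refined = True
    return PeakResult(radius_um=radius, value=vmax, index=i, tie=tie, refined=refined)


def estimate_baseline(profile: RadialProfile, peak: PeakResult) -> float:
    """Pedestal level under the peak: median of a band flanking it.

    The initial width guess w0 comes from the zero-baseline half-maximum
    crossings; the baseline is the median of covered bins whose distance
    from the peak lies in [w0, 2 w0] — far enough out that the peak's own
    tails have died off, close enough in to track the local pedestal of a
    branched background rather than the empty far field. Falls back to all
    bins beyond w0, then to 0 for a peak filling the whole profile.
    """
    w0 = _crossing_width(profile, peak, level=peak.value / 2.0)
    if w0 is None:
        w0 = 3.0 * profile.bin_width_um
    dist = np.abs(profile.radii_um - peak.radius_um)
    covered = profile.n_pixels_per_bin > 0
    band = (dist >= w0) & (dist <= 2.0 * w0) & covered
    if not band.any():
        band = (dist >= w0) & covered
    if not band.any():
        return 0.0
    return float(np.median(profile.values[band]))


def _crossing_width(profile: RadialProfile, peak: PeakResult, level: float) -> float | None:
    left = _cross(profile, peak.index, level, direction=-1)
    right = _cross(profile, peak.index, level, direction=+1)
    if left is None or right is None:
        return None
    return right - left


def _cross(profile: RadialProfile, i_peak: int, level: float, direction: int) -> float | None:
    """Radius where the profile first falls through ``level`` on one side,
    located by linear interpolation between adjacent bins."""
    vals = profile.values
    radii = profile.radii_um
    i = i_peak
    while 0 <= i + direction < len(vals):
        j = i + direction
        if vals[j] < level:
            v0, v1 = vals[i], vals[j]
            if v0 == v1:
                return float(radii[j])
            frac = (v0 - level) / (v0 - v1)
            return float(radii[i] + frac * (radii[j] - radii[i]))
        i = j
    return None


def profile_fwhm(
    profile: RadialProfile,
    peak: PeakResult,
    baseline: float | str = "auto",
) -> FWHMResult | None:
    """Full width at half maximum of the peak, in microns.

    The half-maximum level is baseline + (peak - baseline)/2, with the
    baseline either supplied or estimated from the profile pedestal
    (``"auto"``). Crossings are located by linear interpolation. If the
    half level is never crossed on one side (truncated ring), the width is
    reported as twice the available half-width and flagged one-sided.
    """
    base = estimate_baseline(profile, peak) if baseline == "auto" else float(baseline)
    half = base + (peak.value - base) / 2.0
    if half <= base:
        return None
    left = _cross(profile, peak.index, half, direction=-1)
    right = _cross(profile, peak.index, half, direction=+1)
    if left is None and right is None:
        return None
    peak_r = float(profile.radii_um[peak.index])
    if left is None:
        return FWHMResult(2.0 * (right - peak_r), None, right, base, one_sided=True)
    if right is None:
        return FWHMResult(2.0 * (peak_r - left), left, None, base, one_sided=True)
    return FWHMResult(right - left, left, right, base, one_sided=False)


def profile_auc(profile: RadialProfile, r_range: tuple[float, float] | None = None) -> float:
    """Trapezoidal integral of the profile over a radius range (AU x um)."""
    radii = profile.radii_um
    if r_range is None:
        sel = np.ones(len(radii), dtype=bool)
    else:
        r0, r1 = r_range
        if r1 <= r0:
            raise ValueError("empty radius range")
        sel = (radii >= r0) & (radii <= r1)
    if sel.sum() < 2:
        raise ValueError("radius range covers fewer than two bins")
    return float(np.trapezoid(profile.values[sel], radii[sel]))
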