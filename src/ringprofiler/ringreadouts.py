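"""Biological readouts derived from radial profiles.

A single measurement run goes center -> profile -> peak -> FWHM -> AUC ->
continuity and assembles a :class:`RingMeasurement`. Diameter is twice the
peak radius; thickness is the FWHM of the mean-aggregated profile; AUC and
the peak-intensity continuity proxy come from the sum-aggregated profile
(under which peak intensity is exactly proportional to the fraction of the
ring present, for fixed geometry and amplitude).

Continuity is reported two ways: the peak-intensity proxy (the field's
readout, which confounds amplitude and continuity) and a direct
angular-occupancy index (the fraction of 1-degree angular sectors of the
measured annulus that contain signal), which serves as its independent check.
Images without a characteristic profile peak — e.g. homogeneously seeded
networks — yield a no-peak record with absent readouts, never zeros.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from skimage.filters import threshold_otsu

from .io_imaging import ImageFrame
from .radialprofile import (
    CenterEstimate,
    RadialProfile,
    PeakResult,
    compute_radial_profile,
    estimate_baseline,
    estimate_center,
    profile_auc,
    profile_fwhm,
    profile_peak,
)


@dataclass
class RingMeasurement:
    """Readouts of one ring image; all None when no characteristic peak."""

    diameter_um: float | None
    thickness_um: float | None
    peak_intensity_AU: float | None
    auc_AU_um: float | None
    continuity_index: float | None
    flags: tuple[str, ...] = ()
    day: int | None = None
    provenance: str = ""
    center: CenterEstimate | None = None
    profile: RadialProfile | None = field(default=None, repr=False)

    @property
    def has_ring(self) -> bool:
        return "no-peak" not in self.flags


def measure_ring(
    frame: ImageFrame,
    *,
    center_method: str = "intensity_centroid",
    center: CenterEstimate | None = None,
    bin_width_um: float | None = None,
    baseline: float | str = "auto",
    min_prominence: float = 0.6,
    min_peak_width_um: float = 150.0,
    min_pixels_per_bin: int = 16,
    smooth_um: float = 20.0,
    refine_peak: bool = True,
    day: int | None = None,
) -> RingMeasurement:
    """Measure diameter, thickness, peak intensity, AUC and continuity.

    A peak is considered characteristic of a ring only if (a) its prominence
    over the profile's global-median pedestal exceeds ``min_prominence`` of
    the peak value and (b) its width at the half-prominence level is at least
    ``min_peak_width_um``. The width floor encodes that a patterned cell
    condensate is an order of magnitude wider than single capillaries, so
    chance filament clumps in homogeneous networks — which produce narrow
    bumps at the filament scale — yield a no-peak record at any continuity
    of a genuine ring. Deterministic given the frame and configuration.

    Profiles are lightly smoothed (``smooth_um`` moving average, well below
    the condensate cross-section scale) before peak and width extraction so
    that filament texture crossing the annulus does not jitter the argmax,
    and the ring radius is taken as the midpoint of the half-maximum
    crossings — for a symmetric cross-section this equals the peak position
    and is far more texture-robust than the raw argmax.
    """
    if center is None:
        center = estimate_center(frame, center_method)
    prof_mean = compute_radial_profile(frame, center, bin_width_um=bin_width_um, aggregation="mean")
    if smooth_um and smooth_um > prof_mean.bin_width_um:
        k = max(1, int(round(smooth_um / prof_mean.bin_width_um)))
        from dataclasses import replace as _dc_replace

        smooth_sums = uniform_filter1d(prof_mean.sums, size=k, mode="nearest")
        smooth_counts = uniform_filter1d(
            prof_mean.n_pixels_per_bin.astype(np.float64), size=k, mode="nearest"
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            smooth_vals = np.where(smooth_counts > 0, smooth_sums / smooth_counts, 0.0)
        prof_mean = _dc_replace(prof_mean, values=smooth_vals, sums=smooth_sums)
    prof_sum = prof_mean.as_aggregation("sum")

    peak = _characteristic_peak(
        prof_mean, min_prominence, min_peak_width_um, min_pixels_per_bin
    )
    if peak is None:
        return RingMeasurement(
            diameter_um=None,
            thickness_um=None,
            peak_intensity_AU=None,
            auc_AU_um=None,
            continuity_index=None,
            flags=("no-peak",),
            day=day,
            provenance=frame.provenance,
            center=center,
            profile=prof_mean,
        )

    flags: list[str] = []
    if peak.tie:
        flags.append("tie")
    radius_um = _refine_radius(prof_mean, peak) if refine_peak else peak.radius_um
    fwhm = profile_fwhm(prof_mean, peak, baseline=baseline)
    thickness = fwhm.width_um if fwhm is not None else None
    if fwhm is not None and not fwhm.one_sided:
        # midpoint of the half-maximum crossings: equals the peak position
        # for a symmetric cross-section, robust to crest texture
        radius_um = (fwhm.left_um + fwhm.right_um) / 2.0
    if fwhm is not None and fwhm.one_sided:
        flags.append("one-sided-fwhm")
    if thickness is None:
        flags.append("no-fwhm")
    auc = profile_auc(prof_sum)
    peak_sum = float(prof_sum.values[peak.index])

    meas = RingMeasurement(
        diameter_um=2.0 * radius_um,
        thickness_um=thickness,
        peak_intensity_AU=peak_sum,
        auc_AU_um=auc,
        continuity_index=None,
        flags=tuple(flags),
        day=day,
        provenance=frame.provenance,
        center=center,
        profile=prof_mean,
    )
    if thickness is not None:
        try:
            meas.continuity_index = continuity_angular_index(frame, meas)
        except ValueError:
            meas.flags = meas.flags + ("no-continuity",)
    return meas


def _characteristic_peak(
    profile: RadialProfile,
    min_prominence: float,
    min_peak_width_um: float,
    min_pixels_per_bin: int,
) -> PeakResult | None:
    """Brightest local maximum that qualifies as a condensate-ring peak.

    Candidates (local maxima on adequately covered bins) are visited in
    descending height; the first whose prominence over the global-median
    pedestal and whose width at the half-prominence level both qualify is
    the ring peak. Narrow bright spikes — noise or a filament clump in a
    sparsely covered inner bin — are thereby skipped rather than masking a
    genuine ring crest further out. A qualifying peak must also be a true
    annulus: its radius must be at least its own width, otherwise the
    "ring" would enclose the profile origin (a disk — typically the center
    estimate sitting on a bright structure, not a patterned ring).
    """
    vals = profile.values
    covered = profile.n_pixels_per_bin > 0
    if not covered.any():
        return None
    pedestal = float(np.median(vals[covered]))
    eligible = profile.n_pixels_per_bin >= min_pixels_per_bin
    n = len(vals)
    candidates = [
        i
        for i in range(n)
        if eligible[i]
        and vals[i] > 0
        and (i == 0 or vals[i] >= vals[i - 1])
        and (i == n - 1 or vals[i] >= vals[i + 1])
    ]
    candidates.sort(key=lambda i: vals[i], reverse=True)
    vmax = vals[candidates[0]] if candidates else 0.0
    for i in candidates[:8]:
        value = float(vals[i])
        prominence = (value - pedestal) / value if value > 0 else 0.0
        if prominence < min_prominence:
            break  # lower candidates are only less prominent
        peak = PeakResult(
            radius_um=float(profile.radii_um[i]),
            value=value,
            index=i,
            tie=bool(np.count_nonzero(vals == vmax) > 1) if value == vmax else False,
        )
        fw = profile_fwhm(profile, peak, baseline=pedestal)
        if (
            fw is not None
            and fw.width_um >= min_peak_width_um
            and peak.radius_um >= fw.width_um
        ):
            return peak
    return None


def _refine_radius(profile: RadialProfile, peak: PeakResult) -> float:
    """Three-point parabolic refinement around a chosen peak index."""
    vals = profile.values
    i = peak.index
    if 0 < i < len(vals) - 1:
        denom = vals[i - 1] - 2.0 * vals[i] + vals[i + 1]
        if denom < 0:
            shift = 0.5 * (vals[i - 1] - vals[i + 1]) / denom
            if abs(shift) <= 1.0:
                return peak.radius_um + shift * profile.bin_width_um
    return peak.radius_um


def continuity_peak_proxy(profile: RadialProfile) -> float:
    """Peak value of the sum-aggregated profile: the continuity readout.

    For fixed ring geometry and amplitude this is proportional to the
    fraction of the circle the ring covers; note it is equally proportional
    to amplitude, which the angular-occupancy index is immune to.
    """
    prof_sum = profile.as_aggregation("sum")
    peak = profile_peak(prof_sum)
    if peak is None:
        raise ValueError("no peak: continuity proxy undefined")
    return peak.value


def continuity_angular_index(
    frame: ImageFrame,
    ring: RingMeasurement,
    n_bins: int = 360,
    threshold: float | str = "otsu",
) -> float:
    """Fraction of angular sectors of the measured annulus that carry signal.

    The annulus is [diameter/2 - thickness/2, diameter/2 + thickness/2]
    around the measurement's center; each of ``n_bins`` angular sectors
    counts as occupied when its mean intensity exceeds the threshold.
    The default threshold is Otsu over the *whole frame*: the frame's
    background provides the reference class that separates occupied from
    empty sectors. (``"otsu_annulus"`` restricts Otsu to annulus pixels,
    which is only well-posed when the ring actually has gaps — on an
    unbroken ring it splits the signal against itself.)
    """
    if ring.diameter_um is None or ring.thickness_um is None or ring.center is None:
        raise ValueError("continuity index requires a measured ring")
    pixels = np.asarray(frame.pixels, dtype=np.float64)
    h, w = pixels.shape
    mpp = frame.microns_per_pixel
    cx, cy = ring.center.x_px, ring.center.y_px
    r_in = ring.diameter_um / 2.0 - ring.thickness_um / 2.0
    r_out = ring.diameter_um / 2.0 + ring.thickness_um / 2.0
    edge_um = min(cx, w - 1 - cx, cy, h - 1 - cy) * mpp
    if r_out > edge_um:
        raise ValueError("annulus extends outside the imaged field")
    y, x = np.mgrid[0:h, 0:w]
    dx = (x - cx) * mpp
    dy = (y - cy) * mpp
    r = np.hypot(dx, dy)
    in_annulus = (r >= max(r_in, 0.0)) & (r <= r_out)
    vals = pixels[in_annulus]
    if vals.size == 0:
        raise ValueError("empty annulus")
    if threshold == "otsu":
        if np.all(pixels == pixels.flat[0]):
            raise ValueError("constant frame: threshold undefined")
        thr = float(threshold_otsu(pixels))
    elif threshold == "otsu_annulus":
        if np.all(vals == vals[0]):
            raise ValueError("constant annulus: threshold undefined")
        thr = float(threshold_otsu(vals))
    else:
        thr = float(threshold)
    theta = np.mod(np.arctan2(dy[in_annulus], dx[in_annulus]), 2.0 * math.pi)
    sector = np.minimum((theta / (2.0 * math.pi) * n_bins).astype(np.intp), n_bins - 1)
    sums = np.bincount(sector, weights=vals, minlength=n_bins)
    counts = np.bincount(sector, minlength=n_bins)
    occupied = 0
    nonempty = counts > 0
    means = np.zeros(n_bins)
    means[nonempty] = sums[nonempty] / counts[nonempty]
    occupied = int(np.count_nonzero(means[nonempty] > thr))
    return occupied / int(np.count_nonzero(nonempty))


def compare_day_series(
    measurements: list[RingMeasurement], baseline_day: int = 0
) -> pd.DataFrame:
    """Per-day AUC and peak-proxy ratios against a baseline day.

    Ratios below 1 mark days on which the readout fell under its baseline
    (loss of abundance or continuity). Raises if the baseline day is missing
    or carries no ring.
    """
    by_day = {m.day: m for m in measurements}
    if baseline_day not in by_day:
        raise ValueError(f"baseline day {baseline_day} missing from series")
    base = by_day[baseline_day]
    if not base.has_ring or base.auc_AU_um in (None, 0):
        raise ValueError("baseline day has no measurable ring")
    rows = []
    for m in sorted(measurements, key=lambda m: (m.day is None, m.day)):
        if m.has_ring and m.auc_AU_um is not None:
            auc_ratio = m.auc_AU_um / base.auc_AU_um
            peak_ratio = (
                m.peak_intensity_AU / base.peak_intensity_AU
                if base.peak_intensity_AU
                else np.nan
            )
        else:
            auc_ratio = np.nan
            peak_ratio = np.nan
        rows.append(
            {
                "day": m.day,
                "auc_ratio": auc_ratio,
                "peak_ratio": peak_ratio,
                "below_baseline": bool(peak_ratio < 1.0) if np.isfinite(peak_ratio) else None,
                "has_ring": m.has_ring,
            }
        )
    return pd.DataFrame(rows)


_READOUTS = ("diameter_um", "thickness_um", "peak_intensity_AU", "auc_AU_um", "continuity_index")


def summarize_replicates(measurements: list[RingMeasurement]) -> dict:
    """Mean and SD (ddof=1) per readout over replicate measurements.

    Returns ``{"n": ..., "summary": DataFrame, "table": DataFrame}``; no-peak
    replicates are excluded from moments but kept in the per-replicate table.
    """
    if len(measurements) < 2:
        raise ValueError("replicate summary requires n >= 2")
    table = pd.DataFrame(
        [{k: getattr(m, k) for k in _READOUTS} | {"has_ring": m.has_ring} for m in measurements]
    )
    with_ring = table[table["has_ring"]]
    summary = pd.DataFrame(
        {
            "mean": with_ring[list(_READOUTS)].mean(),
            "sd": with_ring[list(_READOUTS)].std(ddof=1),
            "n": with_ring[list(_READOUTS)].count(),
        }
    )
    return {"n": len(measurements), "summary": summary, "table": table}
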