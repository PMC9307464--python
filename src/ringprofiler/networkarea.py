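"""Binary-mask quantification of total network area and its growth over days.

The fluorescent (GFP) network is segmented by a global threshold — Otsu by
default, a fixed level for sensitivity analysis — small speckle objects are
removed, and the total foreground area is reported in square microns.
Longitudinal series are expressed as percent of the baseline-day (-1) area,
the scale on which network growth is conventionally reported (baseline =
100%); a delta convention (baseline = 0%) is available as a switch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import remove_small_objects

from .io_imaging import ImageFrame


@dataclass
class NetworkMask:
    mask: np.ndarray  # boolean, same shape as source
    threshold_method: str  # "otsu" | "fixed"
    threshold_value: float
    min_object_area_um2: float
    microns_per_pixel: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")


@dataclass
class AreaTimecourse:
    """Per-day total area and growth relative to the baseline day."""

    table: pd.DataFrame  # columns: day, total_area_um2, relative_growth_percent
    baseline_day: int
    convention: str  # "percent_of_baseline" | "percent_change"
    group: str | None = None
    replicate: str | None = None


def binarize(
    frame: ImageFrame,
    method: str = "otsu",
    threshold: float | None = None,
    min_object_area_um2: float = 100.0,
) -> NetworkMask:
    """Threshold a frame into a network mask, removing speckle objects.

    Otsu requires a non-degenerate histogram; a constant image raises.
    Deterministic: the applied threshold is recorded on the mask.
    """
    pixels = np.asarray(frame.pixels, dtype=np.float64)
    if method == "otsu":
        if np.all(pixels == pixels.flat[0]):
            raise ValueError("degenerate histogram: image is constant, Otsu undefined")
        thr = float(threshold_otsu(pixels))
    elif method == "fixed":
        if threshold is None:
            raise ValueError("fixed method requires a threshold value")
        thr = float(threshold)
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    mask = pixels > thr
    min_px = int(round(min_object_area_um2 / frame.microns_per_pixel**2))
    if min_px > 1:
        try:
            # objects strictly smaller than min_px are removed
            mask = remove_small_objects(mask, max_size=min_px - 1)
        except TypeError:  # older scikit-image
            mask = remove_small_objects(mask, min_size=min_px)
    return NetworkMask(
        mask=mask,
        threshold_method=method,
        threshold_value=thr,
        min_object_area_um2=min_object_area_um2,
        microns_per_pixel=frame.microns_per_pixel,
    )


def total_area(mask: NetworkMask) -> float:
    """Total foreground area: pixel count x (microns per pixel)^2."""
    return float(np.count_nonzero(mask.mask)) * mask.microns_per_pixel**2


def object_table(mask: NetworkMask) -> pd.DataFrame:
    """Per-object areas (the particle-analysis view of the mask)."""
    labels = label(mask.mask, connectivity=2)
    rows = [
        {"object": p.label, "area_um2": p.area * mask.microns_per_pixel**2}
        for p in regionprops(labels)
    ]
    return pd.DataFrame(rows, columns=["object", "area_um2"])


def binarize_series(
    frames: list[ImageFrame],
    days: list[int],
    baseline_day: int = -1,
    method: str = "otsu",
    threshold: float | None = None,
    min_object_area_um2: float = 100.0,
    lock_threshold: bool = True,
) -> list[NetworkMask]:
    """Threshold a day series of frames consistently.

    With ``lock_threshold`` (default) the threshold is determined once on the
    baseline-day frame and applied to every day. A per-frame auto-threshold
    drifts with the day's foreground mass, which imprints a spurious trend on
    relative-growth curves; locking the level to the baseline removes that
    artifact. ``lock_threshold=False`` restores per-frame thresholding.
    """
    if len(frames) != len(days):
        raise ValueError("frames and days must align")
    if baseline_day not in days:
        raise ValueError(f"baseline day {baseline_day} missing")
    if lock_threshold and method == "otsu":
        base_frame = frames[days.index(baseline_day)]
        base_mask = binarize(base_frame, method="otsu", min_object_area_um2=min_object_area_um2)
        method, threshold = "fixed", base_mask.threshold_value
    return [
        binarize(f, method=method, threshold=threshold, min_object_area_um2=min_object_area_um2)
        for f in frames
    ]


def relative_growth(
    masks: list[NetworkMask],
    days: list[int],
    baseline_day: int = -1,
    convention: str = "percent_of_baseline",
    group: str | None = None,
    replicate: str | None = None,
) -> AreaTimecourse:
    """Express per-day total areas relative to the baseline day.

    ``percent_of_baseline`` reports day -1 as 100%; ``percent_change``
    reports it as 0%. A zero baseline area is an error.
    """
    if len(masks) != len(days):
        raise ValueError("masks and days must align")
    if baseline_day not in days:
        raise ValueError(f"baseline day {baseline_day} missing")
    if convention not in ("percent_of_baseline", "percent_change"):
        raise ValueError(f"unknown convention {convention!r}")
    areas = {d: total_area(m) for d, m in zip(days, masks)}
    base = areas[baseline_day]
    if base == 0:
        raise ValueError("baseline area is zero: relative growth undefined")
    rows = []
    for d in sorted(days):
        pct = areas[d] / base * 100.0
        if convention == "percent_change":
            pct -= 100.0
        rows.append({"day": d, "total_area_um2": areas[d], "relative_growth_percent": pct})
    return AreaTimecourse(
        table=pd.DataFrame(rows),
        baseline_day=baseline_day,
        convention=convention,
        group=group,
        replicate=replicate,
    )
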