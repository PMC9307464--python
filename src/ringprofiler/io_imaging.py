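"""Calibrated image containers, TIFF I/O and Z-projection.

The analysis operates on 2-D grayscale frames obtained by projecting confocal
Z-stacks. Stacks carry their physical calibration (lateral pixel size and axial
slice spacing) so that every downstream readout can be reported in microns.
Tile stitching is out of scope: inputs are assumed already stitched, and the
tile grid is carried as metadata only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile


class CalibrationError(ValueError):
    """Missing or non-physical calibration (pixel size, slice spacing)."""


@dataclass
class ImageFrame:
    """A single calibrated 2-D grayscale image.

    Parameters
    ----------
    pixels : ndarray, shape (H, W)
        Non-negative intensities in arbitrary units.
    microns_per_pixel : float
        Lateral calibration, microns per pixel (> 0).
    provenance : str
        Free-text record of where the frame came from (source path,
        projection method, day label).
    """

    pixels: np.ndarray
    microns_per_pixel: float
    provenance: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"frame must be 2-D, got shape {self.pixels.shape}")
        if self.microns_per_pixel <= 0:
            raise CalibrationError("microns_per_pixel must be > 0")
        if np.any(self.pixels < 0):
            raise ValueError("frame intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def field_um(self) -> tuple[float, float]:
        """Physical extent (height, width) of the frame in microns."""
        h, w = self.pixels.shape
        return (h * self.microns_per_pixel, w * self.microns_per_pixel)


@dataclass
class ImageStack:
    """A calibrated 3-D grayscale Z-stack, axis order (z, y, x)."""

    voxels: np.ndarray
    microns_per_pixel: float
    z_step_um: float
    tile_grid: tuple[int, int] = (1, 1)
    provenance: str = ""
    field_um: tuple[float, float] = field(init=False)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"stack must be 3-D (z, y, x), got {self.voxels.shape}")
        if min(self.voxels.shape) < 1:
            raise ValueError("all stack dimensions must be >= 1")
        if self.microns_per_pixel <= 0 or self.z_step_um <= 0:
            raise CalibrationError("microns_per_pixel and z_step_um must be > 0")
        _, h, w = self.voxels.shape
        self.field_um = (h * self.microns_per_pixel, w * self.microns_per_pixel)

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def depth_um(self) -> float:
        """Axial extent covered by the stack (slices x slice spacing)."""
        return self.n_slices * self.z_step_um


def load_stack(
    path,
    microns_per_pixel: float,
    z_step_um: float,
    channel: int | None = None,
    tile_grid: tuple[int, int] = (1, 1),
) -> ImageStack:
    """Read a single- or multi-page grayscale TIFF as a calibrated stack.

    Single-page files yield a stack with z-size 1. Multi-channel (RGB or
    channel-last) files are rejected unless ``channel`` selects one plane
    explicitly; there is no silent channel guessing.
    """
    if microns_per_pixel is None or z_step_um is None:
        raise CalibrationError("microns_per_pixel and z_step_um are required")
    try:
        data = tifffile.imread(path)
    except Exception as exc:  # tifffile raises several concrete types
        raise IOError(f"could not read TIFF {path!r}: {exc}") from exc
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None, :, :]
    elif data.ndim == 3 and data.shape[-1] in (3, 4) and data.shape[-1] < data.shape[0]:
        # channel-last colour image
        if channel is None:
            raise ValueError(
                f"{path!r} has {data.shape[-1]} colour channels; pass channel= to select one"
            )
        data = data[None, :, :, channel] if data.ndim == 3 else data
    elif data.ndim == 4:
        # (z, y, x, c) or (c, z, y, x): require explicit channel
        if channel is None:
            raise ValueError(f"{path!r} is multi-channel; pass channel= to select one")
        if data.shape[-1] <= 4:
            data = data[..., channel]
        else:
            data = data[channel]
    if data.ndim != 3:
        raise ValueError(f"unsupported TIFF layout in {path!r}: shape {data.shape}")
    return ImageStack(
        voxels=data,
        microns_per_pixel=microns_per_pixel,
        z_step_um=z_step_um,
        tile_grid=tile_grid,
        provenance=f"loaded from {path}",
    )


def z_project_max(stack: ImageStack) -> ImageFrame:
    """Maximum-intensity Z-projection.

    The per-pixel maximum over slices is the standard projection for sparse
    fluorescent networks; a stack with a single slice projects to itself.
    """
    return ImageFrame(
        pixels=stack.voxels.max(axis=0),
        microns_per_pixel=stack.microns_per_pixel,
        provenance=(stack.provenance + "; " if stack.provenance else "") + "z_project_max",
    )


def z_project_mean(stack: ImageStack) -> ImageFrame:
    """Mean-intensity Z-projection (available behind a config switch)."""
    return ImageFrame(
        pixels=stack.voxels.mean(axis=0),
        microns_per_pixel=stack.microns_per_pixel,
        provenance=(stack.provenance + "; " if stack.provenance else "") + "z_project_mean",
    )


def imaged_region_geometry(
    stack: ImageStack | None = None,
    *,
    area_mm2: float | None = None,
    depth_um: float | None = None,
    decimals: int | None = 1,
) -> tuple[float, float]:
    """Imaged area (mm^2) and volume (mm^3) of an acquisition.

    Area is taken from the stack's lateral field unless supplied directly
    (instruments often report the nominal scanned area, which may differ
    from the pixel-grid product). Volume = area x axial depth.
    """
    if area_mm2 is None:
        if stack is None:
            raise ValueError("either a stack or an explicit area_mm2 is required")
        h_um, w_um = stack.field_um
        area_mm2 = (h_um / 1000.0) * (w_um / 1000.0)
    if depth_um is None:
        if stack is None:
            raise CalibrationError("z extent missing: supply a stack or depth_um")
        depth_um = stack.depth_um
    if depth_um <= 0:
        raise CalibrationError("z extent must be > 0")
    volume_mm3 = area_mm2 * (depth_um / 1000.0)
    if decimals is not None:
        area_mm2 = round(area_mm2, decimals)
        volume_mm3 = round(volume_mm3, decimals)
    return area_mm2, volume_mm3


def write_frame(path, frame: ImageFrame) -> None:
    """Write a frame as a 16-bit grayscale TIFF (values clipped to uint16)."""
    data = np.clip(np.rint(np.asarray(frame.pixels, dtype=np.float64)), 0, 65535)
    tifffile.imwrite(path, data.astype(np.uint16))


def write_stack(path, frames: list[ImageFrame]) -> None:
    """Write frames as pages of a multi-page 16-bit grayscale TIFF."""
    data = np.stack(
        [np.clip(np.rint(np.asarray(f.pixels, dtype=np.float64)), 0, 65535) for f in frames]
    )
    tifffile.imwrite(path, data.astype(np.uint16))
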