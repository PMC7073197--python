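"""Multichannel z-stack container, TIFF I/O and background-subtracted intensity.

Conventions used throughout the package:

* voxel data are indexed ``(channel, z, y, x)``;
* pixel/voxel coordinates are 0-based and half-open;
* the physical position of a voxel centre is ``index * voxel_size`` along
  each axis, so slice ``k`` of a stack with ``dz`` µm spacing sits at
  ``z = k * dz`` µm;
* z index 0 is the lowest z (the substrate side, below the basement
  membrane); cells seeded on top of the membrane invade toward decreasing z.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "ImageStack",
    "RegionOfInterest",
    "read_stack",
    "write_stack",
    "quantify_intensity",
]


@dataclass
class ImageStack:
    """A multichannel 3D image with physical voxel sizes.

    Parameters
    ----------
    data:
        Nonnegative intensities, shape ``(n_channels, nz, ny, nx)``.
    voxel_size_um:
        ``(dz, dy, dx)`` in µm; all strictly positive.
    channels:
        Unique channel labels, one per channel.
    """

    data: np.ndarray
    voxel_size_um: tuple[float, float, float]
    channels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(
                f"stack data must be (channel, z, y, x); got ndim={self.data.ndim}"
            )
        if any(s < 1 for s in self.data.shape):
            raise ValueError(f"all stack dimensions must be >= 1; got {self.data.shape}")
        self.voxel_size_um = tuple(float(v) for v in self.voxel_size_um)
        if len(self.voxel_size_um) != 3 or any(v <= 0 for v in self.voxel_size_um):
            raise ValueError(f"voxel sizes must be 3 positive values; got {self.voxel_size_um}")
        if not self.channels:
            self.channels = tuple(f"ch{i}" for i in range(self.data.shape[0]))
        self.channels = tuple(self.channels)
        if len(self.channels) != self.data.shape[0]:
            raise ValueError("number of channel labels must match the channel axis")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError(f"channel labels must be unique; got {self.channels}")

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.data.shape

    def channel(self, label: str) -> np.ndarray:
        """Return the ``(z, y, x)`` volume for a channel label."""
        try:
            idx = self.channels.index(label)
        except ValueError:
            raise KeyError(f"no channel {label!r}; have {self.channels}") from None
        return self.data[idx]

    def z_positions_um(self) -> np.ndarray:
        """Physical z of each slice centre (µm), index 0 lowest."""
        return np.arange(self.data.shape[1]) * self.voxel_size_um[0]


@dataclass
class RegionOfInterest:
    """A labelled set of pixel (y, x) or voxel (z, y, x) coordinates."""

    label: str
    coords: np.ndarray  # (n, 2) or (n, 3) integer coordinates

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=np.intp))
        if self.coords.size == 0:
            raise ValueError(f"ROI {self.label!r} is empty")
        if self.coords.shape[1] not in (2, 3):
            raise ValueError("ROI coordinates must be (y, x) or (z, y, x)")

    def index_into(self, image: np.ndarray) -> np.ndarray:
        """Pixel values of this ROI in `image`, validating bounds."""
        if self.coords.shape[1] != image.ndim:
            raise ValueError(
                f"ROI {self.label!r} has {self.coords.shape[1]}-d coordinates "
                f"but the image is {image.ndim}-d"
            )
        if (self.coords < 0).any() or (self.coords >= np.array(image.shape)).any():
            raise ValueError(f"ROI {self.label!r} extends outside the image bounds")
        return image[tuple(self.coords.T)]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(stack: ImageStack, path: str | Path, *, force: bool = False) -> Path:
    """Write a stack as a multipage TIFF plus a JSON metadata sidecar.

    Pages are ordered channel-major (all z of channel 0, then channel 1, ...).
    The sidecar records voxel sizes, channel labels and the page layout so the
    round trip through :func:`read_stack` is lossless.
    """
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True to overwrite")
    c, z = stack.shape[:2]
    pages = stack.data.reshape(c * z, *stack.shape[2:])
    tifffile.imwrite(path, pages, photometric="minisblack")
    meta = {
        "voxel_size_um": list(stack.voxel_size_um),
        "channels": list(stack.channels),
        "shape_czyx": list(stack.shape),
        "dtype": str(stack.data.dtype),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_stack(
    path: str | Path,
    *,
    voxel_size_um: tuple[float, float, float] | None = None,
    channels: tuple[str, ...] | None = None,
    n_channels: int | None = None,
) -> ImageStack:
    """Read a multipage TIFF written by :func:`write_stack` (or a plain one).

    Without a sidecar, ``voxel_size_um`` must be given (there is no safe
    default for physical calibration) and the page axis is split into
    ``n_channels`` channel-major blocks (default 1).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim != 3:
        raise ValueError(f"expected uniform 2D pages in {path}; got shape {pages.shape}")

    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        c, z, y, x = meta["shape_czyx"]
        data = pages.reshape(c, z, y, x)
        return ImageStack(
            data,
            voxel_size_um or tuple(meta["voxel_size_um"]),
            channels or tuple(meta["channels"]),
        )

    if voxel_size_um is None:
        raise ValueError(
            f"{path} has no metadata sidecar; pass voxel_size_um=(dz, dy, dx) explicitly"
        )
    c = n_channels or 1
    if pages.shape[0] % c:
        raise ValueError(f"{pages.shape[0]} pages do not split into {c} channels")
    data = pages.reshape(c, pages.shape[0] // c, *pages.shape[1:])
    return ImageStack(data, voxel_size_um, channels or ())


def quantify_intensity(
    image: np.ndarray,
    marker_region: RegionOfInterest,
    background_region: RegionOfInterest,
) -> float:
    """Background-subtracted marker intensity of a region.

    Returns ``mean(marker pixels) - mean(background pixels)`` — the standard
    immunofluorescence readout. The arithmetic mean is used with no trimming,
    and a negative result (marker dimmer than background) is returned as-is.
    Overlapping regions are legal but warn, since the background then contains
    marker signal.
    """
    image = np.asarray(image)
    marker = marker_region.index_into(image)
    background = background_region.index_into(image)
    if marker_region.coords.shape[1] == background_region.coords.shape[1]:
        a = {tuple(c) for c in marker_region.coords}
        b = {tuple(c) for c in background_region.coords}
        if a & b:
            warnings.warn(
                f"marker ROI {marker_region.label!r} overlaps background ROI "
                f"{background_region.label!r}",
                stacklevel=2,
            )
    return float(marker.mean() - background.mean())
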