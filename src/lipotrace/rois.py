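"""Multi-channel field images and per-cell regions of interest.

Every per-cell measurement in this package (co-localization regression,
lipid-raft CT-B metrics) is computed over a :class:`CellROI` — one connected
pixel region per detected T cell.  Detection replaces manual outlining with a
reproducible chain: Gaussian smooth -> threshold (Otsu or fixed) -> hole fill
-> connected components -> area/circularity filter.  Externally drawn ROIs can
be imported from a label-mask TIFF so real data can bypass detection.

Coordinates are 0-based ``(row, col)``; pixel regions are 8-connected.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops


class ChannelNotFoundError(KeyError):
    """Requested channel name is not present in the field image."""


class RoiIntegrityError(ValueError):
    """ROI refers to pixels outside the image or is otherwise inconsistent."""


@dataclass
class FieldImage:
    """Named multi-channel 2-D intensity raster for one microscopy field.

    Parameters
    ----------
    channels
        Mapping channel name -> 2-D array of non-negative intensities.  All
        channels must share one shape.
    pixel_size_um
        Optional physical pixel size in micrometres (metadata only).
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("FieldImage requires at least one channel")
        shapes = {np.asarray(a).shape for a in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels have differing shapes: {shapes}")
        (shape,) = shapes
        if len(shape) != 2:
            raise ValueError("channels must be 2-D arrays")
        self.channels = {k: np.asarray(v) for k, v in self.channels.items()}
        for name, arr in self.channels.items():
            if np.any(arr < 0):
                raise ValueError(f"channel {name!r} has negative intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise ChannelNotFoundError(
                f"channel {name!r} not found; available: {sorted(self.channels)}"
            ) from None

    # ------------------------------------------------------------------ I/O
    def to_tiff(self, path) -> None:
        """Write as a multi-page TIFF, one page per channel, names in metadata."""
        names = list(self.channels)
        stack = np.stack([self.channels[n] for n in names])
        meta = {"channel_names": names, "pixel_size_um": self.pixel_size_um}
        tifffile.imwrite(
            path, stack, description=json.dumps(meta), photometric="minisblack"
        )

    @classmethod
    def from_tiff(cls, path, channel_names: list[str] | None = None) -> "FieldImage":
        with tifffile.TiffFile(path) as tif:
            stack = tif.asarray()
            desc = tif.pages[0].description
        pixel_size = None
        if channel_names is None:
            try:
                meta = json.loads(desc)
                channel_names = meta["channel_names"]
                pixel_size = meta.get("pixel_size_um")
            except (json.JSONDecodeError, KeyError, TypeError):
                raise ValueError(
                    "TIFF lacks channel-name metadata; pass channel_names explicitly"
                )
        if stack.ndim == 2:
            stack = stack[None]
        if len(channel_names) != stack.shape[0]:
            raise ValueError(
                f"{len(channel_names)} channel names for {stack.shape[0]} pages"
            )
        return cls(dict(zip(channel_names, stack)), pixel_size_um=pixel_size)


@dataclass
class CellROI:
    """One connected pixel region for one detected T cell."""

    cell_id: int
    pixels: np.ndarray  # (n, 2) int array of (row, col)
    centroid: tuple[float, float]
    area: int
    channel: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=int)
        if self.pixels.ndim != 2 or self.pixels.shape[1] != 2:
            raise RoiIntegrityError("pixels must be an (n, 2) array of (row, col)")
        if self.area != len(self.pixels):
            raise RoiIntegrityError("area does not match pixel count")

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.pixels[:, 0], self.pixels[:, 1]] = True
        return m


@dataclass
class SegmentationConfig:
    """Parameters of the reproducible cell-detection chain."""

    smoothing_sigma: float = 2.0
    threshold_method: str = "otsu"  # "otsu" | "fixed"
    fixed_threshold: float | None = None
    min_area: int = 50
    max_area: int = 100_000
    min_circularity: float = 0.5

    def __post_init__(self) -> None:
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError("threshold_method must be 'otsu' or 'fixed'")
        if self.threshold_method == "fixed" and self.fixed_threshold is None:
            raise ValueError("fixed_threshold required for method 'fixed'")
        if not self.min_area < self.max_area:
            raise ValueError("min_area must be < max_area")
        if not 0.0 <= self.min_circularity <= 1.0:
            raise ValueError("min_circularity must lie in [0, 1]")


def detect_cells(
    image: FieldImage,
    channel: str = "membrane",
    config: SegmentationConfig | None = None,
) -> list[CellROI]:
    """Detect cells on one channel and return disjoint ROIs, one per cell.

    ROIs are ordered by centroid (row, then col) for determinism.  A blank or
    saturated-everywhere channel yields an empty list with a warning.
    """
    config = config or SegmentationConfig()
    raw = np.asarray(image.channel(channel), dtype=float)
    smooth = (
        ndimage.gaussian_filter(raw, config.smoothing_sigma)
        if config.smoothing_sigma > 0
        else raw
    )
    if config.threshold_method == "otsu":
        if np.ptp(smooth) == 0:
            warnings.warn(
                "channel is constant (blank or saturated); no cells detected",
                stacklevel=2,
            )
            return []
        thresh = threshold_otsu(smooth)
    else:
        thresh = config.fixed_threshold
    mask = smooth > thresh
    mask = ndimage.binary_fill_holes(mask)
    labels = cc_label(mask, connectivity=2)

    rois: list[CellROI] = []
    for prop in regionprops(labels):
        if not config.min_area <= prop.area <= config.max_area:
            continue
        if prop.perimeter > 0:
            circularity = min(1.0, 4.0 * np.pi * prop.area / prop.perimeter**2)
        else:
            circularity = 1.0
        if circularity < config.min_circularity:
            continue
        rois.append(
            CellROI(
                cell_id=-1,
                pixels=prop.coords,
                centroid=tuple(prop.centroid),
                area=int(prop.area),
                channel=channel,
            )
        )
    rois.sort(key=lambda r: r.centroid)
    for i, roi in enumerate(rois):
        roi.cell_id = i
    return rois


def roi_pixels(
    roi: CellROI, image: FieldImage, channel: str
) -> tuple[np.ndarray, np.ndarray]:
    """Return (coordinates, intensities) for one ROI on one channel.

    Intensity order matches coordinate order; length equals the ROI area.
    """
    arr = image.channel(channel)
    rows, cols = roi.pixels[:, 0], roi.pixels[:, 1]
    if (
        rows.size
        and (
            rows.min() < 0
            or cols.min() < 0
            or rows.max() >= arr.shape[0]
            or cols.max() >= arr.shape[1]
        )
    ):
        raise RoiIntegrityError(
            f"ROI {roi.cell_id} has pixels outside image bounds {arr.shape}"
        )
    return roi.pixels, arr[rows, cols]


def rois_from_label_mask(mask: np.ndarray) -> list[CellROI]:
    """Import externally drawn ROIs from an integer label mask (0 = background)."""
    mask = np.asarray(mask)
    rois: list[CellROI] = []
    for prop in regionprops(mask.astype(int)):
        rois.append(
            CellROI(
                cell_id=-1,
                pixels=prop.coords,
                centroid=tuple(prop.centroid),
                area=int(prop.area),
                channel="label_mask",
            )
        )
    rois.sort(key=lambda r: r.centroid)
    for i, roi in enumerate(rois):
        roi.cell_id = i
    return rois


def rois_to_label_mask(rois: list[CellROI], shape: tuple[int, int]) -> np.ndarray:
    """Render ROIs as a label mask (cell_id + 1; 0 = background)."""
    out = np.zeros(shape, dtype=np.int32)
    for roi in rois:
        out[roi.pixels[:, 0], roi.pixels[:, 1]] = roi.cell_id + 1
    return out


def rois_to_table(rois: list[CellROI]) -> pd.DataFrame:
    """Summary table (cell_id, centroid_row, centroid_col, area) for CSV export."""
    return pd.DataFrame(
        {
            "cell_id": [r.cell_id for r in rois],
            "centroid_row": [r.centroid[0] for r in rois],
            "centroid_col": [r.centroid[1] for r in rois],
            "area": [r.area for r in rois],
        }
    )
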