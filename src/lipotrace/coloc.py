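"""Per-cell Bodipy/PLIN2 co-localization classification.

For each cell the ``k`` brightest pixels of the reference (neutral-lipid)
channel are selected and the PLIN2 intensity at those same pixels is regressed
on the Bodipy intensity by ordinary least squares.  A cell is called
co-localizing ("positive") when the regression slope is positive and the
slope t-test is significant at ``alpha``.  The population readout is the
percentage of positive cells per condition.

No multiple-testing correction is applied across cells: the procedure
classifies each cell at raw p < alpha by design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .rois import CellROI, FieldImage, roi_pixels


@dataclass
class ColocConfig:
    """Classifier settings.

    ``sidedness`` chooses how "significant positive correlation" is read:
    ``"two_sided_and_positive_slope"`` (default; two-sided slope p < alpha
    AND slope > 0, i.e. what standard regression software reports) or
    ``"one_sided_positive"`` (one-sided p of the positive-slope alternative).
    """

    k: int = 50
    alpha: float = 0.05
    sidedness: str = "two_sided_and_positive_slope"
    min_pixels: int = 3

    def __post_init__(self) -> None:
        if self.k < 3:
            raise ValueError("k must be >= 3")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.sidedness not in (
            "two_sided_and_positive_slope",
            "one_sided_positive",
        ):
            raise ValueError(f"unknown sidedness {self.sidedness!r}")


@dataclass
class ColocCellResult:
    """Regression outcome for one cell."""

    cell_id: int
    n_pixels: int
    slope: float
    intercept: float
    r: float
    p: float
    positive: bool
    undersized: bool
    degenerate: bool = False


@dataclass
class ColocSummary:
    """Population percentage of co-localizing cells for one condition."""

    condition: str
    n_cells: int
    n_positive: int

    @property
    def percent_positive(self) -> float:
        return 100.0 * self.n_positive / self.n_cells

    def __str__(self) -> str:  # reported to one decimal
        return (
            f"{self.condition}: {self.n_positive}/{self.n_cells} cells "
            f"positive ({self.percent_positive:.1f}%)"
        )


def top_pixels(
    roi: CellROI, image: FieldImage, ref_channel: str = "bodipy", k: int = 50
) -> tuple[np.ndarray, bool]:
    """Select the min(k, area) ROI pixels brightest in the reference channel.

    Ties at the cutoff are broken by raster order (row, then col) so the
    selection is deterministic.  Returns ``(coords, undersized)`` where
    ``undersized`` flags ROIs smaller than ``k``.
    """
    coords, intensities = roi_pixels(roi, image, ref_channel)
    if len(coords) == 0:
        raise ValueError("cannot select pixels from an empty ROI")
    # lexsort: last key is primary -> descending intensity, then row, then col
    order = np.lexsort((coords[:, 1], coords[:, 0], -np.asarray(intensities, float)))
    take = min(k, len(coords))
    return coords[order[:take]], len(coords) < k


def classify_cell(
    pixels: np.ndarray,
    image: FieldImage,
    x_channel: str = "bodipy",
    y_channel: str = "plin2",
    config: ColocConfig | None = None,
    cell_id: int = -1,
    undersized: bool = False,
) -> ColocCellResult:
    """OLS of y-channel on x-channel over the selected pixels.

    The p-value is the slope t-test with n - 2 degrees of freedom.  Constant
    x gives a degenerate result (slope NaN, p = 1, positive False); constant
    y gives slope 0, positive False.
    """
    config = config or ColocConfig()
    pixels = np.asarray(pixels, dtype=int)
    x = np.asarray(image.channel(x_channel)[pixels[:, 0], pixels[:, 1]], dtype=float)
    y = np.asarray(image.channel(y_channel)[pixels[:, 0], pixels[:, 1]], dtype=float)
    n = len(x)
    if n < config.min_pixels:
        return ColocCellResult(
            cell_id, n, np.nan, np.nan, np.nan, 1.0, False, True, degenerate=True
        )
    if np.ptp(x) == 0:
        return ColocCellResult(
            cell_id, n, np.nan, np.nan, 0.0, 1.0, False, undersized, degenerate=True
        )
    if np.ptp(y) == 0:
        return ColocCellResult(
            cell_id, n, 0.0, float(y[0]), 0.0, 1.0, False, undersized
        )
    fit = stats.linregress(x, y)
    if config.sidedness == "one_sided_positive":
        p = fit.pvalue / 2.0 if fit.slope > 0 else 1.0 - fit.pvalue / 2.0
    else:
        p = fit.pvalue
    positive = bool(fit.slope > 0 and p < config.alpha)
    return ColocCellResult(
        cell_id=cell_id,
        n_pixels=n,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        p=float(p),
        positive=positive,
        undersized=undersized,
    )


def classify_field(
    image: FieldImage,
    rois: list[CellROI],
    x_channel: str = "bodipy",
    y_channel: str = "plin2",
    config: ColocConfig | None = None,
) -> list[ColocCellResult]:
    """Run top-pixel selection + regression for every ROI in a field."""
    config = config or ColocConfig()
    results = []
    for roi in rois:
        pix, undersized = top_pixels(roi, image, x_channel, config.k)
        results.append(
            classify_cell(
                pix,
                image,
                x_channel,
                y_channel,
                config,
                cell_id=roi.cell_id,
                undersized=undersized,
            )
        )
    return results


def summarize(
    results: list[ColocCellResult],
    condition: str = "",
    include_undersized: bool = False,
) -> ColocSummary:
    """Percentage of positive cells over classified (non-undersized) cells."""
    kept = [
        r
        for r in results
        if not r.degenerate and (include_undersized or not r.undersized)
    ]
    if not kept:
        raise ValueError("no classifiable cells to summarize")
    return ColocSummary(
        condition=condition,
        n_cells=len(kept),
        n_positive=sum(r.positive for r in kept),
    )


def intensity_profile(
    image: FieldImage,
    start: tuple[float, float],
    end: tuple[float, float],
    channels: list[str] | None = None,
) -> dict[str, np.ndarray]:
    """Gray-value traces along a line (nearest-pixel sampling), per channel.

    Diagnostic counterpart of the cross-sectional spatial plots used to eyeball
    co-occurrence; every returned trace has the same number of samples.
    """
    start = np.asarray(start, float)
    end = np.asarray(end, float)
    length = np.hypot(*(end - start))
    if length == 0:
        raise ValueError("zero-length profile line")
    shape = image.shape
    for pt in (start, end):
        if not (0 <= pt[0] < shape[0] and 0 <= pt[1] < shape[1]):
            raise ValueError(f"profile endpoint {tuple(pt)} outside image {shape}")
    n = int(np.ceil(length)) + 1
    rows = np.clip(np.round(np.linspace(start[0], end[0], n)).astype(int), 0, shape[0] - 1)
    cols = np.clip(np.round(np.linspace(start[1], end[1], n)).astype(int), 0, shape[1] - 1)
    names = channels if channels is not None else list(image.channels)
    return {name: np.asarray(image.channel(name)[rows, cols], float) for name in names}
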