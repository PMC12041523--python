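"""Lipid-raft abundance and clustering metrics from CT-B fluorescence.

CT-B (cholera toxin subunit B) binds ganglioside GM1, which is enriched in
lipid rafts.  Per cell, the mean CT-B fluorescence over the ROI reads out
total raft abundance, while the maximal fluorescence reads out clustering
(concentrated rafts pile signal into fewer, brighter pixels at fixed total
signal).  Fields are summarized by averaging the per-cell metrics over all
T cells in the field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rois import CellROI, FieldImage, roi_pixels


@dataclass
class RaftMetrics:
    """Per-cell CT-B readouts; max_ctb >= mean_ctb >= 0 always holds."""

    cell_id: int
    mean_ctb: float
    max_ctb: float


@dataclass
class FieldRaftSummary:
    """Arithmetic means of the per-cell metrics over one field."""

    field_id: str
    n_cells: int
    mean_of_means: float
    mean_of_maxima: float


def cell_ctb_metrics(
    roi: CellROI,
    image: FieldImage,
    ctb_channel: str = "ctb",
    top_fraction: float | None = None,
) -> RaftMetrics:
    """Mean and max CT-B intensity over all ROI pixels.

    ``top_fraction`` switches the clustering readout from the single maximum
    pixel to the mean of the brightest ``top_fraction`` of pixels (e.g. 0.01),
    which is robust to hot pixels; default is the plain maximum.
    """
    if roi.area == 0:
        raise ValueError("empty ROI")
    _, intensities = roi_pixels(roi, image, ctb_channel)
    intensities = np.asarray(intensities, dtype=float)
    if top_fraction is None:
        max_ctb = float(intensities.max())
    else:
        if not 0 < top_fraction <= 1:
            raise ValueError("top_fraction must lie in (0, 1]")
        k = max(1, int(round(top_fraction * intensities.size)))
        max_ctb = float(np.sort(intensities)[-k:].mean())
    return RaftMetrics(
        cell_id=roi.cell_id,
        mean_ctb=float(intensities.mean()),
        max_ctb=max_ctb,
    )


def field_average(metrics: list[RaftMetrics], field_id: str = "") -> FieldRaftSummary:
    """Average the per-cell metrics over one field (one dot per field)."""
    if not metrics:
        raise ValueError("cannot summarize an empty field")
    return FieldRaftSummary(
        field_id=field_id,
        n_cells=len(metrics),
        mean_of_means=float(np.mean([m.mean_ctb for m in metrics])),
        mean_of_maxima=float(np.mean([m.max_ctb for m in metrics])),
    )
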