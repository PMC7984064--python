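"""Apical-to-lateral membrane signal ratio — the polarity index.

The index for one cell is the mean voxel intensity over an apical membrane
ROI divided by the mean over a lateral membrane ROI, optionally after
subtracting a background ROI mean from both.  Ratios are computed per cell
and then aggregated as mean ± SD across cells.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .datatypes import ImageStack, MembraneROI, PolarityResult


def roi_mean(stack: ImageStack, roi: MembraneROI) -> float:
    """Mean intensity over every voxel of the ROI."""
    return float(roi.extract(stack).mean())


def apical_lateral_ratio(
    stack: ImageStack,
    apical_roi: MembraneROI,
    lateral_roi: MembraneROI,
    background_roi: Optional[MembraneROI] = None,
    cell_id: Optional[str] = None,
) -> PolarityResult:
    """Polarity index of one cell.

    With a background ROI the ratio is
    ``(apical - background) / (lateral - background)``; the denominator must
    stay positive.
    """
    apical = roi_mean(stack, apical_roi)
    lateral = roi_mean(stack, lateral_roi)
    background = roi_mean(stack, background_roi) if background_roi is not None else None
    denom = lateral - (background or 0.0)
    if denom <= 0:
        raise ValueError("lateral mean must exceed the background; ratio undefined")
    ratio = (apical - (background or 0.0)) / denom
    return PolarityResult(
        apical_mean=apical,
        lateral_mean=lateral,
        background_mean=background,
        ratio=ratio,
        cell_id=cell_id,
    )


def aggregate_polarity(results: Sequence[PolarityResult]) -> tuple[float, float]:
    """Mean ± sample SD of per-cell ratios (SD is 0 for a single cell)."""
    if len(results) == 0:
        raise ValueError("no per-cell results to aggregate")
    ratios = np.asarray([r.ratio for r in results], dtype=float)
    sd = float(ratios.std(ddof=1)) if len(ratios) > 1 else 0.0
    return float(ratios.mean()), sd
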