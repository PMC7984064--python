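"""Thresholding-free confocal cluster detection.

The detector works on the maximum-intensity projection (MIP) of a membrane
ROI.  It finds strict local maxima (each brighter than all eight in-plane
neighbours), then classifies the size of each maximum by dilating a square
window around it — ``(2n+1) x (2n+1)`` pixels for radius ``n`` — until some
pixel in the window becomes brighter than the peak.  The largest passing
radius defines the size class ``side_px = 2 * n_max + 1``, converted to a
physical diameter via the lateral pixel size.  No absolute intensity
threshold enters the detection: only intensity *ranks* matter, so the result
is invariant under adding or positively rescaling intensities.

Calls whose window growth was stopped by the image border or by the radius
cap are marked ``capped`` and excluded from the size gate.  Calls whose
3x3 neighbourhood mean falls below a low percentile of the plane are flagged
``low_contrast``; this is a reproducible surrogate for discarding false
positives (a bright pixel in an otherwise dim area) by eye.
"""

from __future__ import annotations

from typing import Optional, Sequence, Union

import numpy as np
from skimage.filters import threshold_otsu

from .datatypes import ClusterCall, DensityResult, ImageStack, MembraneROI, PlaneImage

DEFAULT_N_CAP = 6  # largest window radius tried; side 13 px, above the gate anyway
DEFAULT_MIN_SIDE_PX = 5
DEFAULT_MAX_SIDE_PX = 9
DEFAULT_LOW_CONTRAST_PERCENTILE = 90.0


def project_membrane(stack: ImageStack, roi: MembraneROI) -> PlaneImage:
    """Maximum-intensity projection of a membrane ROI along its normal axis.

    The two non-projected axes keep their order; their voxel sizes become
    the plane's pixel sizes.
    """
    sub = roi.extract(stack)
    ax = roi.projection_axis_index
    if sub.shape[ax] < 1:
        raise ValueError("degenerate ROI: zero thickness along the projection axis")
    plane = sub.max(axis=ax)
    sizes = [v for i, v in enumerate(stack.voxel_size_zyx_um) if i != ax]
    return PlaneImage(data=plane, pixel_size_um=(sizes[0], sizes[1]))


def find_local_maxima(plane: PlaneImage) -> list[tuple[int, int]]:
    """Strict 8-neighbour local maxima of the plane, excluding the border.

    A pixel qualifies only if it is strictly brighter than all eight
    neighbours; plateaus and border pixels are never peaks.
    """
    a = np.asarray(plane.data, dtype=float)
    if a.shape[0] < 3 or a.shape[1] < 3:
        raise ValueError("plane must be at least 3x3")
    c = a[1:-1, 1:-1]
    mask = np.ones_like(c, dtype=bool)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            mask &= c > a[1 + dr : a.shape[0] - 1 + dr, 1 + dc : a.shape[1] - 1 + dc]
    rows, cols = np.nonzero(mask)
    return [(int(r) + 1, int(c_) + 1) for r, c_ in zip(rows, cols)]


def estimate_cluster_size(
    plane: PlaneImage,
    peak: tuple[int, int],
    n_cap: int = DEFAULT_N_CAP,
    alt_2n_convention: bool = False,
) -> ClusterCall:
    """Grow square windows around a local maximum to classify its size.

    ``n_max`` is the largest radius ``n <= n_cap`` such that no pixel in the
    ``(2n+1) x (2n+1)`` window is strictly brighter than the peak.  Growth
    that runs into the image border or reaches ``n_cap`` marks the call
    ``capped``.  With ``alt_2n_convention`` the reported size class is
    ``2 * n_max`` instead of ``2 * n_max + 1`` (an alternative reading of the
    same construction; the default odd convention matches the retained
    5–9 px range).
    """
    if n_cap < 1:
        raise ValueError("n_cap must be >= 1")
    a = np.asarray(plane.data, dtype=float)
    r, c = peak
    if not (1 <= r < a.shape[0] - 1 and 1 <= c < a.shape[1] - 1):
        raise ValueError(f"peak {peak} lacks a complete 3x3 neighbourhood")
    v = a[r, c]
    neigh = a[r - 1 : r + 2, c - 1 : c + 2].copy()
    neigh[1, 1] = -np.inf
    if not np.all(v > neigh):
        raise ValueError(f"pixel {peak} is not a strict local maximum")

    n_max = 1
    capped = False
    while n_max < n_cap:
        n = n_max + 1
        if r - n < 0 or c - n < 0 or r + n >= a.shape[0] or c + n >= a.shape[1]:
            capped = True  # next window would be truncated by the border
            break
        window = a[r - n : r + n + 1, c - n : c + n + 1]
        if np.any(window > v):
            break
        n_max = n
    else:
        capped = True  # growth terminated only by the configured cap

    side_px = 2 * n_max if alt_2n_convention else 2 * n_max + 1
    lateral = min(plane.pixel_size_um)
    return ClusterCall(
        peak=(int(r), int(c)),
        n_max=n_max,
        side_px=side_px,
        diameter_um=to_physical_diameter(side_px, lateral),
        capped=capped,
    )


def flag_low_contrast(
    plane: PlaneImage,
    calls: Sequence[ClusterCall],
    percentile: float = DEFAULT_LOW_CONTRAST_PERCENTILE,
) -> list[ClusterCall]:
    """Flag calls whose 3x3 neighbourhood mean is dim relative to the plane.

    The threshold is the given percentile of all plane intensities.  Flagged
    calls are candidates for the false-positive class the original procedure
    discarded manually; nothing is dropped here.
    """
    a = np.asarray(plane.data, dtype=float)
    cutoff = float(np.percentile(a, percentile))
    out = []
    for call in calls:
        r, c = call.peak
        local_mean = float(a[r - 1 : r + 2, c - 1 : c + 2].mean())
        out.append(
            ClusterCall(
                peak=call.peak,
                n_max=call.n_max,
                side_px=call.side_px,
                diameter_um=call.diameter_um,
                capped=call.capped,
                low_contrast=local_mean < cutoff,
            )
        )
    return out


def filter_size_classes(
    calls: Sequence[ClusterCall],
    min_side_px: int = DEFAULT_MIN_SIDE_PX,
    max_side_px: int = DEFAULT_MAX_SIDE_PX,
    drop_low_contrast: bool = False,
) -> list[ClusterCall]:
    """Retain calls whose size class lies in the gate and that are not capped."""
    if min_side_px > max_side_px:
        raise ValueError("min_side_px must not exceed max_side_px")
    kept = [
        c
        for c in calls
        if (min_side_px <= c.side_px <= max_side_px)
        and not c.capped
        and not (drop_low_contrast and c.low_contrast)
    ]
    return kept


def to_physical_diameter(side_px: int, lateral_pixel_size_um: float) -> float:
    """Convert a pixel size class to a physical diameter in µm (full precision)."""
    if side_px < 1:
        raise ValueError("side_px must be >= 1")
    if lateral_pixel_size_um <= 0:
        raise ValueError("pixel size must be positive")
    return side_px * lateral_pixel_size_um


def printed_diameter(diameter_um: float, decimals: int = 2, truncate: bool = False) -> float:
    """Display rounding of a diameter; ``truncate`` floors instead of rounding."""
    scale = 10**decimals
    if truncate:
        return int(diameter_um * scale) / scale
    return round(diameter_um, decimals)


def estimate_membrane_area(
    plane: PlaneImage, threshold: Union[str, float] = "otsu"
) -> float:
    """Membrane area (µm²) from brightness thresholding of the projection.

    ``threshold`` is either ``"otsu"`` or an absolute intensity value;
    pixels at or above it count as membrane.
    """
    a = np.asarray(plane.data, dtype=float)
    if a.size == 0:
        raise ValueError("empty plane")
    t = float(threshold_otsu(a)) if threshold == "otsu" else float(threshold)
    n_above = int(np.count_nonzero(a >= t))
    if n_above == 0:
        raise ValueError("no pixels at or above the threshold; membrane area undefined")
    return n_above * plane.pixel_area_um2


def cluster_density(roi_id: str, n_peaks: int, n_retained: int, membrane_area_um2: float) -> DensityResult:
    """Cluster density = retained calls per membrane area (µm⁻²)."""
    if membrane_area_um2 <= 0:
        raise ValueError("membrane area must be positive")
    return DensityResult(
        roi_id=roi_id,
        n_peaks=n_peaks,
        n_retained=n_retained,
        membrane_area_um2=float(membrane_area_um2),
        density_per_um2=n_retained / membrane_area_um2,
    )


def quantify_roi(
    stack: ImageStack,
    roi: MembraneROI,
    min_side_px: int = DEFAULT_MIN_SIDE_PX,
    max_side_px: int = DEFAULT_MAX_SIDE_PX,
    n_cap: int = DEFAULT_N_CAP,
    area_threshold: Union[str, float] = "otsu",
    low_contrast_percentile: float = DEFAULT_LOW_CONTRAST_PERCENTILE,
    drop_low_contrast: bool = False,
    alt_2n_convention: bool = False,
) -> tuple[DensityResult, list[ClusterCall]]:
    """Run the full per-ROI pipeline: MIP, maxima, sizes, gate, area, density.

    Returns the density summary together with *all* calls (flagged, capped
    and out-of-gate calls included) so downstream reporting can audit the
    gating.
    """
    plane = project_membrane(stack, roi)
    peaks = find_local_maxima(plane)
    calls = [estimate_cluster_size(plane, p, n_cap=n_cap, alt_2n_convention=alt_2n_convention) for p in peaks]
    calls = flag_low_contrast(plane, calls, percentile=low_contrast_percentile)
    retained = filter_size_classes(
        calls, min_side_px=min_side_px, max_side_px=max_side_px, drop_low_contrast=drop_low_contrast
    )
    area = estimate_membrane_area(plane, threshold=area_threshold)
    result = cluster_density(roi.id, n_peaks=len(peaks), n_retained=len(retained), membrane_area_um2=area)
    return result, calls
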