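"""Post-classification cleanup: sieve noise removal and the multi-temporal
saturation-consistency correction.

The sieve removes connected clusters of non-vegetation smaller than a minimum
pixel count, merging them back into vegetation — small non-vegetation specks
at sub-meter resolution are overwhelmingly tree-occlusion shadows and sensor
noise rather than real impervious features. The pixel threshold is held at a
fixed ground area (9 m^2 by default, the footprint of a 3x3 kernel at 1 m) so
it adapts to the image resolution: 9 px at 1 m, and 3.24 m^2 = 9 px at 0.6 m.

An acquisition whose NIR response saturates (its radiometric response
plateaus at high radiance) under-detects non-vegetation because impervious
NDVI is inflated. The correction anchors the suspect year's non-vegetation
mask on stable features seen in other surveys:

    corrected = low_ndvi AND (anchor_1 OR anchor_2 OR ... )

where ``low_ndvi`` restricts the transfer to pixels the suspect year itself
considers plausibly non-vegetated (NDVI below a cutoff, 0.15 by default).
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy import ndimage

from .types import BinaryMask, IndexStack

_STRUCTS = {
    4: ndimage.generate_binary_structure(2, 1),
    8: ndimage.generate_binary_structure(2, 2),
}


def scale_sieve_threshold(min_area_m2: float, pixel_size_m: float) -> int:
    """Pixel-count threshold equivalent to a ground area at a resolution.

    ``ceil(min_area_m2 / pixel_size_m^2)``, so 9 m^2 at 1 m and 3.24 m^2 at
    0.6 m both map to 9 pixels.
    """
    if min_area_m2 <= 0 or pixel_size_m <= 0:
        raise ValueError("min_area_m2 and pixel_size_m must be positive")
    ratio = min_area_m2 / (pixel_size_m ** 2)
    # guard against float fuzz turning an exact multiple into ceil(n + eps)
    if math.isclose(ratio, round(ratio), rel_tol=1e-9):
        return int(round(ratio))
    return int(math.ceil(ratio))


def sieve_filter(
    mask: BinaryMask,
    min_pixels: int,
    connectivity: int = 8,
    target: str = "nonveg_clusters",
) -> BinaryMask:
    """Reclassify small non-vegetation clusters as vegetation.

    ``mask`` is TRUE for vegetation. Every connected component of FALSE
    (non-vegetation) pixels with size strictly below ``min_pixels`` is
    flipped to TRUE; components of size >= min_pixels are untouched, so
    size-9 clusters survive the default threshold of 9. Idempotent.
    """
    if min_pixels < 1:
        raise ValueError("min_pixels must be >= 1")
    if connectivity not in _STRUCTS:
        raise ValueError("connectivity must be 4 or 8")
    if target != "nonveg_clusters":
        raise ValueError(f"unknown sieve target {target!r}")
    if min_pixels == 1:
        return BinaryMask(
            values=mask.values.copy(),
            pixel_size_m=mask.pixel_size_m,
            nodata_mask=mask.nodata_mask.copy(),
            geotransform=mask.geotransform,
        )
    nonveg = ~mask.values
    labels, n = ndimage.label(nonveg, structure=_STRUCTS[connectivity])
    out = mask.values.copy()
    if n:
        sizes = np.bincount(labels.ravel())
        small = sizes < min_pixels
        small[0] = False
        out[small[labels]] = True
    return BinaryMask(
        values=out,
        pixel_size_m=mask.pixel_size_m,
        nodata_mask=mask.nodata_mask.copy(),
        geotransform=mask.geotransform,
    )


def build_low_ndvi_mask(idx: IndexStack, ndvi_cutoff: float = 0.15) -> BinaryMask:
    """TRUE where NDVI < cutoff (strict): plausibly non-vegetated pixels."""
    return BinaryMask(
        values=idx.ndvi < ndvi_cutoff,
        pixel_size_m=idx.pixel_size_m,
        nodata_mask=idx.nodata_mask.copy(),
        geotransform=idx.geotransform,
    )


def resample_nearest(values: np.ndarray, out_shape: tuple) -> np.ndarray:
    """Nearest-neighbour resample of a categorical/boolean raster."""
    rows = (np.arange(out_shape[0]) * values.shape[0] / out_shape[0]).astype(int)
    cols = (np.arange(out_shape[1]) * values.shape[1] / out_shape[1]).astype(int)
    return values[np.ix_(rows, cols)]


def saturation_correct(
    m_ndvi: BinaryMask, anchors: Sequence[BinaryMask]
) -> BinaryMask:
    """Anchor a saturated year's non-vegetation mask on other surveys.

    Per pixel: ``low_ndvi AND (anchor_1 OR anchor_2 OR ...)``. Anchor masks
    whose grid differs are nearest-neighbour resampled onto ``m_ndvi``'s
    grid. The result is contained in ``m_ndvi`` and in the anchor union, and
    is monotone non-decreasing in each anchor.
    """
    anchors = list(anchors)
    if not anchors:
        raise ValueError("at least one anchor mask is required")
    union = np.zeros(m_ndvi.shape, dtype=bool)
    for a in anchors:
        vals = a.values
        if vals.shape != m_ndvi.shape:
            vals = resample_nearest(vals, m_ndvi.shape)
        union |= vals
    return BinaryMask(
        values=m_ndvi.values & union,
        pixel_size_m=m_ndvi.pixel_size_m,
        nodata_mask=m_ndvi.nodata_mask.copy(),
        geotransform=m_ndvi.geotransform,
    )
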