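"""Per-pixel classification metrics: NDVI, NDWI, brightness and texture.

NDVI = (NIR - Red) / (NIR + Red) and NDWI = (Green - NIR) / (Green + NIR) are
the standard normalized-difference indices; brightness is the per-pixel sum of
squared DNs over the four bands (DN^2 units, so an 8-bit image is bounded by
4 * 255^2 = 260100); texture is a second-order gray-level co-occurrence
statistic of the NIR band over all 8 neighbour offsets inside a moving window.

The texture statistic, window size and gray-level quantization are
configurable because threshold values are only meaningful relative to them;
defaults are contrast, a 3x3 window (the 8-neighbour adjacency kernel) and 32
gray levels.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np
from scipy import ndimage

from .types import IndexStack, MultibandImage

TEXTURE_STATISTICS = ("contrast", "dissimilarity", "variance")

_OFFSETS_8 = [
    (dy, dx)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dy, dx) != (0, 0)
]


def _normalized_difference(a: np.ndarray, b: np.ndarray, return_flags: bool):
    a = a.astype(np.float64)
    b = b.astype(np.float64)
    denom = a + b
    zero = denom == 0
    out = np.zeros_like(denom)
    np.divide(a - b, denom, out=out, where=~zero)
    return (out, zero) if return_flags else out


def compute_ndvi(img: MultibandImage, return_flags: bool = False):
    """(NIR - Red)/(NIR + Red); zero-denominator pixels -> 0 (flagged)."""
    return _normalized_difference(img.nir, img.red, return_flags)


def compute_ndwi(img: MultibandImage, return_flags: bool = False):
    """(Green - NIR)/(Green + NIR); zero-denominator pixels -> 0 (flagged)."""
    return _normalized_difference(img.green, img.nir, return_flags)


def compute_brightness(img: MultibandImage) -> np.ndarray:
    """Per-pixel Red^2 + Green^2 + Blue^2 + NIR^2 in DN^2 units."""
    b = img.bands.astype(np.float64)
    return (b ** 2).sum(axis=0)


def quantize(values: np.ndarray, bit_depth: int, levels: int) -> np.ndarray:
    """Map DNs in [0, 2^bit_depth - 1] onto integer gray levels [0, levels-1]."""
    q = (values.astype(np.float64) * levels / (2 ** bit_depth)).astype(np.int64)
    return np.clip(q, 0, levels - 1)


def _offset_kernel(window: int, dy: int, dx: int) -> np.ndarray:
    """Indicator over anchor positions p (relative to the window centre) such
    that both p and p + (dy, dx) fall inside the window."""
    r = window // 2
    k = np.zeros((window, window))
    rows = np.arange(-r, r + 1)
    cols = np.arange(-r, r + 1)
    ok_r = (rows >= -r + max(0, -dy)) & (rows <= r - max(0, dy))
    ok_c = (cols >= -r + max(0, -dx)) & (cols <= r - max(0, dx))
    k[np.ix_(ok_r, ok_c)] = 1.0
    return k


def compute_texture(
    img: MultibandImage,
    window: int = 3,
    statistic: str = "contrast",
    levels: int = 32,
) -> np.ndarray:
    """Moving-window co-occurrence texture of the NIR band.

    For every pixel, a symmetric gray-level co-occurrence distribution is
    tallied over all pixel pairs at the 8 unit offsets that lie fully inside
    the centred ``window``; ``statistic`` summarizes it:

    * ``contrast``      sum_ij P(i, j) (i - j)^2
    * ``dissimilarity`` sum_ij P(i, j) |i - j|
    * ``variance``      sum_ij P(i, j) (i - mu)^2, mu the GLCM marginal mean

    Edges are handled by reflection padding. The result is nonnegative and
    exactly zero on constant rasters.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    if statistic not in TEXTURE_STATISTICS:
        raise ValueError(
            f"unknown statistic {statistic!r}; choose from {TEXTURE_STATISTICS}"
        )
    q = quantize(img.nir, img.bit_depth, levels).astype(np.float64)
    r = window // 2
    # pad by r (anchor grid) + 1 (offset reach) so every pair is defined
    qp = np.pad(q, r + 1, mode="reflect")
    h, w = q.shape

    num = np.zeros((h, w))
    cnt = 0.0
    if statistic == "variance":
        s1 = np.zeros((h, w))
        s2 = np.zeros((h, w))
    for dy, dx in _OFFSETS_8:
        # first-element value at each anchor of the padded anchor grid
        a = qp[1 : 1 + h + 2 * r, 1 : 1 + w + 2 * r]
        b = qp[1 + dy : 1 + dy + h + 2 * r, 1 + dx : 1 + dx + w + 2 * r]
        kern = _offset_kernel(window, dy, dx)
        cnt += kern.sum()
        if statistic == "contrast":
            d = (a - b) ** 2
        elif statistic == "dissimilarity":
            d = np.abs(a - b)
        else:  # variance: accumulate first-element moments
            d = None
            s1 += ndimage.correlate(a, kern, mode="constant")[r : r + h, r : r + w]
            s2 += ndimage.correlate(a ** 2, kern, mode="constant")[r : r + h, r : r + w]
        if d is not None:
            num += ndimage.correlate(d, kern, mode="constant")[r : r + h, r : r + w]
    if statistic == "variance":
        mu = s1 / cnt
        out = s2 / cnt - mu ** 2
        return np.maximum(out, 0.0)
    return num / cnt


def compute_index_stack(
    img: MultibandImage,
    window: int = 3,
    statistic: str = "contrast",
    levels: int = 32,
) -> IndexStack:
    """All four metric layers for one image, sharing its grid and nodata."""
    ndvi, ndvi_flags = compute_ndvi(img, return_flags=True)
    ndwi, ndwi_flags = compute_ndwi(img, return_flags=True)
    return IndexStack(
        ndvi=ndvi,
        ndwi=ndwi,
        brightness=compute_brightness(img),
        texture=compute_texture(img, window=window, statistic=statistic, levels=levels),
        nodata_mask=img.nodata_mask.copy(),
        pixel_size_m=img.pixel_size_m,
        geotransform=img.geotransform,
        provenance={
            "year_label": img.year_label,
            "texture_window": window,
            "texture_statistic": statistic,
            "texture_levels": levels,
            "bit_depth": img.bit_depth,
            "zero_denominator": ndvi_flags | ndwi_flags,
        },
    )
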