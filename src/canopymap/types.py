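"""Core raster containers shared by every pipeline stage.

All rasters are row-major numpy arrays indexed ``(row, col)`` with the origin
at the top-left corner; pixels are area cells. Georeferencing is carried as a
GDAL-style 6-tuple ``(x0, dx, rot_x, y0, rot_y, -dy)`` and is treated as an
opaque payload: no stage modifies it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

#: Class codes used in every output map.
TREE = 3
NONVEG = 2
GRASS = 1

#: Nodata sentinel written to class-map files (repo convention).
NODATA_LABEL = 0

BAND_NAMES = ("red", "green", "blue", "nir")

DEFAULT_GEOTRANSFORM = (0.0, 1.0, 0.0, 0.0, 0.0, -1.0)


def _check_2d(name: str, arr: np.ndarray, shape: tuple) -> None:
    if arr.ndim != 2:
        raise ValueError(f"{name} must be 2-D, got ndim={arr.ndim}")
    if arr.shape != shape:
        raise ValueError(f"{name} shape {arr.shape} != expected {shape}")


@dataclass
class MultibandImage:
    """Georeferenced 4-band digital-number raster.

    Bands are stored in the fixed order (red, green, blue, nir) regardless of
    how the source file stored them.
    """

    bands: np.ndarray  # (4, H, W) DN array
    pixel_size_m: float = 1.0
    bit_depth: int = 8
    nodata_mask: Optional[np.ndarray] = None  # True where invalid
    geotransform: tuple = DEFAULT_GEOTRANSFORM
    crs: Optional[str] = None
    year_label: Optional[str] = None

    def __post_init__(self) -> None:
        self.bands = np.asarray(self.bands)
        if self.bands.ndim != 3 or self.bands.shape[0] != 4:
            raise ValueError(
                f"bands must have shape (4, H, W), got {self.bands.shape}"
            )
        if self.pixel_size_m <= 0:
            raise ValueError("pixel_size_m must be positive")
        dn_max = self.dn_max
        if self.bands.min() < 0 or self.bands.max() > dn_max:
            raise ValueError(f"DN values must lie in [0, {dn_max}]")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            _check_2d("nodata_mask", self.nodata_mask, self.shape)

    @property
    def shape(self) -> tuple:
        return self.bands.shape[1:]

    @property
    def dn_max(self) -> int:
        return 2 ** self.bit_depth - 1

    @property
    def red(self) -> np.ndarray:
        return self.bands[0]

    @property
    def green(self) -> np.ndarray:
        return self.bands[1]

    @property
    def blue(self) -> np.ndarray:
        return self.bands[2]

    @property
    def nir(self) -> np.ndarray:
        return self.bands[3]

    def with_bands(self, bands: np.ndarray) -> "MultibandImage":
        """Copy of this image with the DN array replaced."""
        return replace(self, bands=np.asarray(bands))


@dataclass
class BinaryMask:
    """Boolean raster aligned to a source image grid."""

    values: np.ndarray
    pixel_size_m: float = 1.0
    nodata_mask: Optional[np.ndarray] = None
    geotransform: tuple = DEFAULT_GEOTRANSFORM

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("mask values must be 2-D")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            _check_2d("nodata_mask", self.nodata_mask, self.values.shape)

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def __invert__(self) -> "BinaryMask":
        return replace(self, values=~self.values)


@dataclass
class ClassMap:
    """Integer raster over the three product classes.

    Label semantics are fixed: 3 = tree canopy, 2 = non-vegetation,
    1 = grassland; 0 is the nodata sentinel in serialized form (in memory
    nodata is a separate boolean mask).
    """

    labels: np.ndarray
    pixel_size_m: float = 1.0
    nodata_mask: Optional[np.ndarray] = None
    geotransform: tuple = DEFAULT_GEOTRANSFORM
    crs: Optional[str] = None
    year_label: Optional[str] = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be 2-D")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.labels.shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            _check_2d("nodata_mask", self.nodata_mask, self.labels.shape)
        valid = self.labels[~self.nodata_mask]
        if valid.size and not np.isin(valid, (GRASS, NONVEG, TREE)).all():
            bad = np.setdiff1d(np.unique(valid), [GRASS, NONVEG, TREE])
            raise ValueError(f"labels outside {{1,2,3}} on valid pixels: {bad}")

    @property
    def shape(self) -> tuple:
        return self.labels.shape


@dataclass
class IndexStack:
    """Per-pixel spectral/textural metrics aligned to a source image.

    ``ndvi``/``ndwi`` lie in [-1, 1] on valid pixels; ``brightness`` is the
    per-pixel sum of squared DNs over the four bands (DN^2 units); ``texture``
    is a nonnegative co-occurrence statistic of the NIR band.
    """

    ndvi: np.ndarray
    ndwi: np.ndarray
    brightness: np.ndarray
    texture: np.ndarray
    nodata_mask: np.ndarray
    pixel_size_m: float = 1.0
    geotransform: tuple = DEFAULT_GEOTRANSFORM
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shape = np.asarray(self.ndvi).shape
        for name in ("ndvi", "ndwi", "brightness", "texture", "nodata_mask"):
            arr = np.asarray(getattr(self, name))
            _check_2d(name, arr, shape)
            setattr(self, name, arr)
        self.nodata_mask = self.nodata_mask.astype(bool)

    @property
    def shape(self) -> tuple:
        return self.ndvi.shape
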