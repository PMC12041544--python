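"""Raster file I/O with the pipeline's band and nodata conventions enforced.

Two on-disk formats are supported:

* **GeoTIFF** — read and written through :mod:`tifffile`. The geotransform is
  carried via the ModelPixelScale / ModelTiepoint tags and the nodata value
  via the GDAL_NODATA ASCII tag, so outputs open correctly in standard GIS
  tools.
* **ENVI** — a flat band-sequential binary ``.img`` plus a text ``.hdr``.
  The format is a handful of header keywords over raw bytes and is
  implemented here directly.

Conventions: imagery is stored and returned with internal band order
(red, green, blue, nir); a multiband pixel whose four DNs are all zero is
nodata; class maps use 0 as the nodata sentinel (valid labels are 1/2/3).
"""

from __future__ import annotations

import os
from typing import Optional, Sequence

import numpy as np
import tifffile

from .types import (
    BAND_NAMES,
    DEFAULT_GEOTRANSFORM,
    ClassMap,
    MultibandImage,
    NODATA_LABEL,
)

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113

_ENVI_DTYPES = {
    1: np.uint8,
    2: np.int16,
    3: np.int32,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
    13: np.uint32,
}
_ENVI_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


# ---------------------------------------------------------------------------
# geotransform helpers


def _geotransform_pixel_size(gt: tuple) -> float:
    dx, dy = abs(gt[1]), abs(gt[5])
    if not np.isclose(dx, dy):
        raise ValueError(
            f"non-square pixels ({dx} x {dy} m) are not supported; "
            "resample the input first"
        )
    return float(dx)


def _detect_format(path: str, fmt: Optional[str]) -> str:
    if fmt is not None:
        fmt = fmt.lower()
        if fmt not in ("envi", "geotiff"):
            raise ValueError(f"unsupported format {fmt!r}; use 'envi' or 'geotiff'")
        return fmt
    ext = os.path.splitext(path)[1].lower()
    if ext in (".tif", ".tiff"):
        return "geotiff"
    if ext in (".img", ".dat", ".bsq"):
        return "envi"
    raise ValueError(f"cannot infer raster format from extension {ext!r}")


# ---------------------------------------------------------------------------
# GeoTIFF


def _geotiff_extratags(gt: tuple, nodata: Optional[float]):
    dx, dy = abs(gt[1]), abs(gt[5])
    tags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (dx, dy, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, gt[0], gt[3], 0.0)),
    ]
    if nodata is not None:
        s = str(int(nodata)) + "\x00"
        tags.append((_TAG_GDAL_NODATA, "s", len(s), s))
    return tags


def _read_geotiff(path: str):
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        page = tif.pages[0]
        interleaved = page.samplesperpixel > 1 and page.planarconfig != 2
        gt = DEFAULT_GEOTRANSFORM
        scale_tag = page.tags.get(_TAG_MODEL_PIXEL_SCALE)
        tie_tag = page.tags.get(_TAG_MODEL_TIEPOINT)
        if scale_tag is not None and tie_tag is not None:
            dx, dy = scale_tag.value[0], scale_tag.value[1]
            x0, y0 = tie_tag.value[3], tie_tag.value[4]
            gt = (float(x0), float(dx), 0.0, float(y0), 0.0, -float(dy))
    if arr.ndim == 2:
        arr = arr[None]
    elif arr.ndim == 3 and interleaved:
        arr = np.moveaxis(arr, -1, 0)  # (H, W, C) -> (C, H, W)
    return arr, gt


def _write_geotiff(data: np.ndarray, path: str, gt: tuple, nodata: Optional[float]):
    # band-interleaved-by-pixel layout; single band written as plain 2-D
    if data.shape[0] == 1:
        out = data[0]
    else:
        out = np.moveaxis(data, 0, -1)
    tifffile.imwrite(
        path,
        out,
        photometric="minisblack",
        planarconfig="contig" if data.shape[0] > 1 else None,
        extratags=_geotiff_extratags(gt, nodata),
    )


# ---------------------------------------------------------------------------
# ENVI


def _envi_header_path(img_path: str) -> str:
    return os.path.splitext(img_path)[0] + ".hdr"


def _write_envi(data: np.ndarray, path: str, gt: tuple, nodata: Optional[float]):
    nbands, h, w = data.shape
    code = _ENVI_CODES.get(data.dtype)
    if code is None:
        raise ValueError(f"dtype {data.dtype} not representable in ENVI")
    dx, dy = abs(gt[1]), abs(gt[5])
    lines = [
        "ENVI",
        "description = {canopymap raster}",
        f"samples = {w}",
        f"lines = {h}",
        f"bands = {nbands}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {code}",
        "interleave = bsq",
        "byte order = 0",
        f"map info = {{Arbitrary, 1.0, 1.0, {gt[0]}, {gt[3]}, {dx}, {dy}, units=Meters}}",
    ]
    if nodata is not None:
        lines.append(f"data ignore value = {int(nodata)}")
    data.tofile(path)
    with open(_envi_header_path(path), "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _parse_envi_header(hdr_path: str) -> dict:
    with open(hdr_path) as fh:
        text = fh.read()
    fields: dict = {}
    key, buf, in_braces = None, [], False
    for line in text.splitlines():
        if in_braces:
            buf.append(line.strip())
            if "}" in line:
                fields[key] = " ".join(buf).strip("{} ")
                in_braces = False
            continue
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        key, value = key.strip().lower(), value.strip()
        if value.startswith("{") and "}" not in value:
            buf, in_braces = [value.lstrip("{")], True
        else:
            fields[key] = value.strip("{} ")
    return fields

def _read_envi(path: str):
    hdr = _parse_envi_header(_envi_header_path(path))
    h, w = int(hdr["lines"]), int(hdr["samples"])
    nbands = int(hdr["bands"])
    dtype = _ENVI_DTYPES[int(hdr["data type"])]
    interleave = hdr.get("interleave", "bsq").lower()
    raw = np.fromfile(path, dtype=dtype)
    if raw.size != nbands * h * w:
        raise ValueError(f"ENVI payload size mismatch in {path}")
    if interleave == "bsq":
        arr = raw.reshape(nbands, h, w)
    elif interleave == "bil":
        arr = raw.reshape(h, nbands, w).transpose(1, 0, 2)
    elif interleave == "bip":
        arr = raw.reshape(h, w, nbands).transpose(2, 0, 1)
    else:
        raise ValueError(f"unknown interleave {interleave!r}")
    gt = DEFAULT_GEOTRANSFORM
    if "map info" in hdr:
        parts = [p.strip() for p in hdr["map info"].split(",")]
        x0, y0, dx, dy = (float(parts[i]) for i in (3, 4, 5, 6))
        gt = (x0, dx, 0.0, y0, 0.0, -dy)
    nodata = hdr.get("data ignore value")
    return arr, gt, (float(nodata) if nodata is not None else None)


# ---------------------------------------------------------------------------
# public API


def read_multiband(
    path: str,
    band_order: Sequence[str] = BAND_NAMES,
    bit_depth: int = 8,
    year_label: Optional[str] = None,
) -> MultibandImage:
    """Read a >=4-band raster and remap its bands to (red, green, blue, nir).

    Parameters
    ----------
    path
        GeoTIFF (``.tif``) or ENVI (``.img`` with sibling ``.hdr``) file.
    band_order
        Names of the first four bands *as stored in the file*; must be a
        permutation of ``("red", "green", "blue", "nir")``.

    A pixel whose four DNs are all zero is flagged nodata.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    fmt = _detect_format(path, None)
    if fmt == "geotiff":
        arr, gt = _read_geotiff(path)
    else:
        arr, gt, _ = _read_envi(path)
    if arr.shape[0] < 4:
        raise ValueError(f"expected 4 bands, file has {arr.shape[0]}")
    if sorted(band_order) != sorted(BAND_NAMES):
        raise ValueError(
            f"band_order must be a permutation of {BAND_NAMES}, got {band_order}"
        )
    order = [list(band_order).index(name) for name in BAND_NAMES]
    bands = arr[order]
    nodata_mask = (bands == 0).all(axis=0)
    return MultibandImage(
        bands=bands,
        pixel_size_m=_geotransform_pixel_size(gt),
        bit_depth=bit_depth,
        nodata_mask=nodata_mask,
        geotransform=gt,
        year_label=year_label,
    )


def write_multiband(img: MultibandImage, path: str, format: Optional[str] = None) -> None:
    """Write a 4-band image; nodata pixels are zero-filled in every band."""
    fmt = _detect_format(path, format)
    dtype = np.uint8 if img.bit_depth <= 8 else np.uint16
    data = img.bands.astype(dtype).copy()
    data[:, img.nodata_mask] = 0
    if fmt == "geotiff":
        _write_geotiff(data, path, img.geotransform, nodata=0)
    else:
        _write_envi(data, path, img.geotransform, nodata=0)


def write_classmap(cmap: ClassMap, path: str, format: Optional[str] = None) -> None:
    """Write a class map (labels 1/2/3, nodata sentinel 0).

    ENVI output produces a paired ``.img`` + ``.hdr``; GeoTIFF output is a
    single-band uint8 file with GDAL_NODATA = 0.
    """
    fmt = _detect_format(path, format)
    labels = cmap.labels.astype(np.uint8).copy()
    labels[cmap.nodata_mask] = NODATA_LABEL
    data = labels[None]
    if fmt == "geotiff":
        _write_geotiff(data, path, cmap.geotransform, nodata=NODATA_LABEL)
    else:
        _write_envi(data, path, cmap.geotransform, nodata=NODATA_LABEL)


def read_classmap(path: str) -> ClassMap:
    """Read back a class map written by :func:`write_classmap`."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    fmt = _detect_format(path, None)
    if fmt == "geotiff":
        arr, gt = _read_geotiff(path)
    else:
        arr, gt, _ = _read_envi(path)
    labels = arr[0]
    nodata_mask = labels == NODATA_LABEL
    safe = labels.copy()
    safe[nodata_mask] = 1  # placeholder under mask; ClassMap validates valid pixels only
    return ClassMap(
        labels=safe,
        pixel_size_m=_geotransform_pixel_size(gt),
        nodata_mask=nodata_mask,
        geotransform=gt,
    )


def write_mask_geotiff(values: np.ndarray, path: str, geotransform: tuple = DEFAULT_GEOTRANSFORM) -> None:
    """Export a boolean mask as a single-band 0/1 GeoTIFF for inspection."""
    _write_geotiff(values.astype(np.uint8)[None], path, geotransform, nodata=None)
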