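"""End-to-end orchestration of one classification year and of change
summaries between years.

``run_year`` chains: index extraction -> Stage I vegetation delineation ->
sieve noise removal -> (optional) multi-mask saturation correction ->
Stage II tree/grass separation. Every threshold actually applied and the
per-stage pixel tallies are logged, keeping manually refined runs auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .classify import ThresholdConfig, stage1_vegetation_mask, stage2_classify
from .indices import compute_index_stack
from .postprocess import (
    build_low_ndvi_mask,
    resample_nearest,
    saturation_correct,
    sieve_filter,
)
from .types import BinaryMask, ClassMap, GRASS, MultibandImage, NONVEG, TREE

logger = logging.getLogger("canopymap")

CLASS_NAMES = {TREE: "tree", NONVEG: "nonveg", GRASS: "grass"}


def run_year(
    img: MultibandImage,
    cfg: ThresholdConfig,
    anchors: Optional[Sequence[BinaryMask]] = None,
    ndvi_cutoff: float = 0.15,
    return_intermediates: bool = False,
):
    """Classify one year's image into the three product classes.

    ``anchors`` are other years' Stage-I *non-vegetation* masks; when given,
    the saturation-consistency correction replaces this year's non-vegetation
    mask by ``low_ndvi AND (anchor_1 OR ... OR own_mask)`` — the year's own
    mask joins the anchor union, per the correction formula.
    """
    idx = compute_index_stack(
        img,
        window=cfg.texture_window,
        statistic=cfg.texture_statistic,
        levels=cfg.texture_levels,
    )
    logger.info("run_year %s: thresholds %s", cfg.year_label, cfg)
    veg = stage1_vegetation_mask(idx, cfg)
    logger.info("stage1 vegetation pixels: %d", int(veg.values.sum()))
    veg = sieve_filter(veg, cfg.sieve_min_pixels, cfg.connectivity)
    logger.info("post-sieve vegetation pixels: %d", int(veg.values.sum()))
    if anchors:
        m_ndvi = build_low_ndvi_mask(idx, ndvi_cutoff)
        corrected = saturation_correct(m_ndvi, list(anchors) + [~veg])
        veg = ~corrected
        logger.info(
            "saturation-corrected non-vegetation pixels: %d",
            int(corrected.values.sum()),
        )
    cmap = stage2_classify(idx, veg, cfg)
    for label, name in CLASS_NAMES.items():
        logger.info(
            "final %s pixels: %d",
            name,
            int((cmap.labels[~cmap.nodata_mask] == label).sum()),
        )
    if return_intermediates:
        return cmap, {"indices": idx, "vegetation_mask": veg}
    return cmap


def coverage_stats(cmap: ClassMap, boundary=None) -> pd.DataFrame:
    """Per-class pixel counts and fractions of valid pixels.

    ``boundary`` is an optional shapely polygon in map coordinates; pixels
    whose centres fall outside it are excluded.
    """
    valid = ~cmap.nodata_mask
    if boundary is not None:
        import shapely

        gt = cmap.geotransform
        rows, cols = np.nonzero(valid)
        x = gt[0] + (cols + 0.5) * gt[1]
        y = gt[3] + (rows + 0.5) * gt[5]
        inside = shapely.contains_xy(boundary, x, y)
        keep = np.zeros_like(valid)
        keep[rows[inside], cols[inside]] = True
        valid = keep
    total = int(valid.sum())
    if total == 0:
        raise ValueError("no valid pixels in the (clipped) map")
    labels = cmap.labels[valid]
    rows = []
    for label in (GRASS, NONVEG, TREE):
        n = int((labels == label).sum())
        rows.append({
            "class": CLASS_NAMES[label],
            "label": label,
            "pixels": n,
            "fraction": n / total,
        })
    return pd.DataFrame(rows).set_index("label")


def _align(map_a: ClassMap, map_b: ClassMap) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Common-grid label arrays and co-valid mask; the coarser map is
    nearest-neighbour resampled onto the finer grid."""
    a_lab, a_nod = map_a.labels, map_a.nodata_mask
    b_lab, b_nod = map_b.labels, map_b.nodata_mask
    if a_lab.shape != b_lab.shape:
        if map_a.pixel_size_m >= map_b.pixel_size_m:
            a_lab = resample_nearest(a_lab, b_lab.shape)
            a_nod = resample_nearest(a_nod, b_lab.shape)
        else:
            b_lab = resample_nearest(b_lab, a_lab.shape)
            b_nod = resample_nearest(b_nod, a_lab.shape)
    covalid = ~(a_nod | b_nod)
    if not covalid.any():
        raise ValueError("maps share no valid pixels")
    return a_lab, b_lab, covalid


def change_map(map_a: ClassMap, map_b: ClassMap) -> Tuple[np.ndarray, pd.DataFrame]:
    """Class transitions between two maps.

    Returns a per-pixel transition-code raster (``10*label_a + label_b``, 0
    where either map is nodata) and a 3x3 count matrix (rows = first map,
    cols = second) whose total equals the number of co-valid pixels.
    """
    a_lab, b_lab, covalid = _align(map_a, map_b)
    codes = np.zeros(a_lab.shape, dtype=np.int64)
    codes[covalid] = 10 * a_lab[covalid] + b_lab[covalid]
    classes = (GRASS, NONVEG, TREE)
    counts = np.zeros((3, 3), dtype=np.int64)
    for i, la in enumerate(classes):
        sel = covalid & (a_lab == la)
        for j, lb in enumerate(classes):
            counts[i, j] = int((b_lab[sel] == lb).sum())
    names = [CLASS_NAMES[c] for c in classes]
    matrix = pd.DataFrame(counts, index=names, columns=names)
    return codes, matrix


@dataclass
class RunManifest:
    """Declarative description of a multi-year processing run."""

    entries: List[dict] = field(default_factory=list)
    # each entry: {"year": str, "image": MultibandImage or path,
    #              "config": ThresholdConfig, "anchor_years": [str, ...],
    #              "ndvi_cutoff": float}
    seed: int = 0

    def __post_init__(self) -> None:
        years = [str(e["year"]) for e in self.entries]
        if len(set(years)) != len(years):
            raise ValueError("manifest years must be unique")
        for e in self.entries:
            for ay in e.get("anchor_years", []):
                if str(ay) not in years:
                    raise ValueError(f"anchor year {ay!r} not in manifest")


def run_manifest(manifest: RunManifest) -> Dict[str, ClassMap]:
    """Run every year; years with ``anchor_years`` get the saturation
    correction using the other years' post-sieve non-vegetation masks."""
    from .raster_io import read_multiband

    images: Dict[str, MultibandImage] = {}
    for e in manifest.entries:
        img = e["image"]
        images[str(e["year"])] = (
            img if isinstance(img, MultibandImage) else read_multiband(img)
        )
    # first pass: uncorrected runs, keeping the post-sieve vegetation masks
    masks: Dict[str, BinaryMask] = {}
    results: Dict[str, ClassMap] = {}
    for e in manifest.entries:
        year = str(e["year"])
        cmap, inter = run_year(
            images[year], e["config"], return_intermediates=True
        )
        masks[year] = inter["vegetation_mask"]
        results[year] = cmap
    # second pass: corrected years
    for e in manifest.entries:
        if not e.get("anchor_years"):
            continue
        year = str(e["year"])
        anchors = [~masks[str(a)] for a in e["anchor_years"]]
        results[year] = run_year(
            images[year],
            e["config"],
            anchors=anchors,
            ndvi_cutoff=e.get("ndvi_cutoff", 0.15),
        )
    return results
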