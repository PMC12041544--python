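"""Synthetic sub-meter 4-band scene generator with exact ground truth.

Scenes emulate leaf-on aerial survey imagery over a managed urban landscape:

* **grassland** — bright, spectrally uniform, texturally smooth (small
  additive DN noise);
* **tree canopy** — darker, strongly NIR-reflective, and rough: every crown
  pixel carries an independent multiplicative illumination factor emulating
  within-crown leaf occlusion and self-shadowing. Because the factor scales
  all four bands equally it moves brightness and texture a lot while leaving
  the normalized-difference indices untouched, which is exactly the contrast
  the two-stage classifier exploits;
* **water** — dark with green > NIR (positive NDWI);
* **impervious / roof / bare soil** — non-vegetated surfaces; "roof" is a
  bright material whose NIR/red ratio nudges NDVI above the Stage-I cutoff
  so only the Node-1 brightness rule catches it;
* **cast shadows** — crown silhouettes displaced along the anti-solar
  direction, darkened in every band but most strongly in NIR (shade is lit
  by NIR-poor diffuse skylight), so shadows trip the Stage-I non-vegetation
  rule the way real occlusion shadows do. The truth label under a shadow
  remains the underlying surface;
* an optional **NIR saturation** artifact: a compressive plateau in the NIR
  response that inflates the NDVI of impervious surfaces.

Scene layout is fixed by the patch list in the spec; the ``seed`` drives only
radiometric noise, so two specs differing only in seed share identical truth.
All randomness uses numpy's PCG64 generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .types import BinaryMask, ClassMap, GRASS, MultibandImage, NONVEG, TREE

#: surface type -> (truth label, band means (R,G,B,NIR), additive sigma,
#: multiplicative speckle sigma)
DEFAULT_RADIOMETRY: Dict[str, dict] = {
    "grass": dict(label=GRASS, mean=(90, 110, 70, 180), sigma=4.0, speckle=0.0),
    "tree": dict(label=TREE, mean=(60, 80, 55, 150), sigma=2.0, speckle=0.35,
                 gain_range=(0.85, 1.30), speckle_base=0.25,
                 speckle_slope=0.8, speckle_jitter=0.04),
    "water": dict(label=NONVEG, mean=(30, 60, 70, 20), sigma=3.0, speckle=0.0),
    "impervious": dict(label=NONVEG, mean=(150, 145, 135, 115), sigma=4.0, speckle=0.0),
    "roof": dict(label=NONVEG, mean=(220, 220, 215, 200), sigma=5.0, speckle=0.0),
    "soil": dict(label=NONVEG, mean=(155, 140, 100, 120), sigma=4.0, speckle=0.0),
}


@dataclass
class Patch:
    """One painted region: an axis-aligned rectangle or a disc."""

    surface: str
    shape: str  # "rect" | "disc"
    params: tuple  # rect: (row0, col0, height, width); disc: (row, col, radius)

    def raster(self, shape: Tuple[int, int]) -> np.ndarray:
        h, w = shape
        if self.shape == "rect":
            r0, c0, ph, pw = self.params
            m = np.zeros(shape, dtype=bool)
            m[max(r0, 0) : min(r0 + ph, h), max(c0, 0) : min(c0 + pw, w)] = True
            return m
        if self.shape == "disc":
            r, c, rad = self.params
            yy, xx = np.ogrid[:h, :w]
            return (yy - r) ** 2 + (xx - c) ** 2 <= rad ** 2
        raise ValueError(f"unknown patch shape {self.shape!r}")


@dataclass
class SceneSpec:
    """Parametric description of one synthetic scene."""

    height: int = 256
    width: int = 256
    pixel_size_m: float = 1.0
    bit_depth: int = 8
    seed: int = 0
    patches: List[Patch] = field(default_factory=list)
    radiometry: Dict[str, dict] = field(default_factory=lambda: {
        k: dict(v) for k, v in DEFAULT_RADIOMETRY.items()
    })
    # shadow model
    shadows_on: bool = True
    sun_azimuth_deg: float = 225.0
    sun_elevation_deg: float = 70.0
    tree_height_m: float = 6.0
    shadow_factor: float = 0.35
    shadow_nir_factor: float = 0.12
    # NIR saturation artifact
    saturation_on: bool = False
    saturation_plateau_dn: float = 230.0
    saturation_knee_dn: float = 60.0
    saturation_tau_dn: float = 60.0
    year_label: Optional[str] = None

    def replace(self, **kwargs) -> "SceneSpec":
        return replace(self, **kwargs)


def default_scene_spec(
    height: int = 256,
    width: int = 256,
    pixel_size_m: float = 1.0,
    layout_seed: int = 0,
    seed: Optional[int] = None,
    tree_cluster_density: float = 1 / 1600.0,
    **kwargs,
) -> SceneSpec:
    """A calibrated mixed urban scene: roads, buildings, water, bare soil,
    clustered tree crowns over a grassland background.

    ``layout_seed`` fixes the patch layout; ``seed`` (defaults to
    ``layout_seed``) drives only the radiometric noise.
    """
    rng = np.random.default_rng(layout_seed)
    patches: List[Patch] = []
    # bare soil lot
    patches.append(Patch("soil", "rect", (
        int(rng.integers(0, height // 2)), int(rng.integers(0, width // 2)),
        height // 8, width // 6)))
    # pond
    patches.append(Patch("water", "disc", (
        int(rng.integers(height // 4, 3 * height // 4)),
        int(rng.integers(width // 4, 3 * width // 4)),
        max(4, height // 12))))
    # road cross
    road_w = max(3, height // 50)
    patches.append(Patch("impervious", "rect",
                         (int(rng.integers(0, height)), 0, road_w, width)))
    patches.append(Patch("impervious", "rect",
                         (0, int(rng.integers(0, width)), height, road_w)))
    # buildings: a few mid-gray and a few bright-roof rectangles
    for surface, count in (("impervious", 4), ("roof", 3)):
        for _ in range(count):
            bh, bw = int(rng.integers(8, 16)), int(rng.integers(8, 16))
            patches.append(Patch(surface, "rect", (
                int(rng.integers(0, height - bh)),
                int(rng.integers(0, width - bw)), bh, bw)))
    # clustered tree crowns
    n_clusters = max(3, int(round(height * width * tree_cluster_density)))
    for _ in range(n_clusters):
        cr = int(rng.integers(0, height))
        cc = int(rng.integers(0, width))
        for _ in range(int(rng.integers(8, 14))):
            rr = int(np.clip(cr + rng.integers(-14, 15), 0, height - 1))
            c2 = int(np.clip(cc + rng.integers(-14, 15), 0, width - 1))
            patches.append(Patch("tree", "disc", (rr, c2, int(rng.integers(2, 5)))))
    return SceneSpec(
        height=height,
        width=width,
        pixel_size_m=pixel_size_m,
        seed=layout_seed if seed is None else seed,
        patches=patches,
        **kwargs,
    )


def _paint(spec: SceneSpec) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Surface-type index raster, truth labels and per-crown id raster,
    by draw order (later patches overwrite earlier ones)."""
    surfaces = list(spec.radiometry)
    surface_idx = {name: i for i, name in enumerate(surfaces)}
    surf = np.full((spec.height, spec.width), surface_idx["grass"], dtype=np.int64)
    crown_id = np.full((spec.height, spec.width), -1, dtype=np.int64)
    n_crowns = 0
    for patch in spec.patches:
        sel = patch.raster((spec.height, spec.width))
        surf[sel] = surface_idx[patch.surface]
        if patch.surface == "tree":
            crown_id[sel] = n_crowns
            n_crowns += 1
        else:
            crown_id[sel] = -1
    labels = np.empty_like(surf)
    for name, i in surface_idx.items():
        labels[surf == i] = spec.radiometry[name]["label"]
    return surf, labels, crown_id


def cast_shadows(
    img: MultibandImage,
    truth: ClassMap,
    sun_azimuth_deg: float,
    sun_elevation_deg: float,
    tree_height_m: float = 6.0,
    shadow_factor: float = 0.35,
    shadow_nir_factor: float = 0.12,
) -> Tuple[MultibandImage, np.ndarray]:
    """Darken ground pixels in the anti-solar shadow of tree crowns.

    The crown silhouette (truth label 3) is swept ``L = height / (pixel_size
    * tan(elevation))`` pixels toward the anti-solar azimuth; swept pixels
    outside the canopy itself are darkened (visible bands by
    ``shadow_factor``, NIR by the stronger ``shadow_nir_factor``). Canopy
    self-shading is part of the crown speckle model, so crown pixels are
    excluded. Returns the modified image and the boolean shadow mask.
    """
    if not 0.0 < sun_elevation_deg <= 90.0:
        raise ValueError("sun elevation must lie in (0, 90] degrees")
    crowns = truth.labels == TREE
    length = tree_height_m / (img.pixel_size_m * math.tan(math.radians(sun_elevation_deg)))
    n = int(round(length))
    az = math.radians(sun_azimuth_deg)
    # azimuth 0 = sun due north -> shadow due south (+row); east = +col
    dr, dc = math.cos(az), -math.sin(az)
    shadow = np.zeros_like(crowns)
    for t in range(1, n + 1):
        sr, sc = int(round(dr * t)), int(round(dc * t))
        shifted = np.zeros_like(crowns)
        rs0, rs1 = max(sr, 0), min(crowns.shape[0] + sr, crowns.shape[0])
        cs0, cs1 = max(sc, 0), min(crowns.shape[1] + sc, crowns.shape[1])
        shifted[rs0:rs1, cs0:cs1] = crowns[rs0 - sr : rs1 - sr, cs0 - sc : cs1 - sc]
        shadow |= shifted
    shadow &= ~crowns
    bands = img.bands.astype(np.float64).copy()
    for b, f in enumerate([shadow_factor] * 3 + [shadow_nir_factor]):
        bands[b][shadow] *= f
    out = img.with_bands(np.clip(np.round(bands), 0, img.dn_max).astype(img.bands.dtype))
    return out, shadow


def apply_saturation(
    img: MultibandImage,
    plateau_dn: float = 230.0,
    knee_dn: float = 60.0,
    tau_dn: float = 60.0,
) -> MultibandImage:
    """Pass the NIR band through a compressive plateau.

    DNs up to the knee are unchanged; above it the response decays
    exponentially toward ``plateau_dn``, compressing high-NIR contrast and
    lifting moderate NIR values — the signature that inflates impervious
    NDVI. A knee at the DN ceiling is the identity.
    """
    if not 0 <= plateau_dn <= img.dn_max:
        raise ValueError("plateau_dn outside DN range")
    nir = img.nir.astype(np.float64)
    over = nir > knee_dn
    out = nir.copy()
    out[over] = knee_dn + (plateau_dn - knee_dn) * (
        1.0 - np.exp(-(nir[over] - knee_dn) / tau_dn)
    )
    bands = img.bands.astype(np.float64).copy()
    bands[3] = out
    return img.with_bands(np.clip(np.round(bands), 0, img.dn_max).astype(img.bands.dtype))


def generate_scene(spec: SceneSpec) -> Tuple[MultibandImage, ClassMap, pd.DataFrame]:
    """Render a scene: (image, truth map, per-surface bookkeeping table).

    Deterministic given ``spec`` (noise from ``spec.seed``); overlapping
    patches are resolved by draw order (later wins). The bookkeeping table
    has one row per surface type with its truth label, exact pixel count and
    area fraction.
    """
    rng = np.random.default_rng(spec.seed)
    surf, labels, crown_id = _paint(spec)
    shape = (spec.height, spec.width)
    dn_max = 2 ** spec.bit_depth - 1
    bands = np.zeros((4,) + shape, dtype=np.float64)
    surfaces = list(spec.radiometry)
    n_crowns = int(crown_id.max()) + 1
    for i, name in enumerate(surfaces):
        sel = surf == i
        if not sel.any():
            continue
        entry = spec.radiometry[name]
        n = int(sel.sum())
        base = np.array(entry["mean"], dtype=np.float64)[:, None]
        vals = base + rng.normal(0.0, entry["sigma"], size=(4, n))
        if name == "tree" and "gain_range" in entry and n_crowns:
            # per-crown illumination gain and roughness: crowns differ by
            # species, age and sun-facing geometry; brighter (more exposed)
            # crowns also show stronger within-crown shading contrast
            g_lo, g_hi = entry["gain_range"]
            crown_gain = rng.uniform(g_lo, g_hi, size=n_crowns)
            crown_speckle = np.clip(
                entry["speckle_base"]
                + entry["speckle_slope"] * (crown_gain - g_lo)
                + rng.normal(0.0, entry["speckle_jitter"], size=n_crowns),
                0.08,
                0.5,
            )
            ids = crown_id[sel]
            z = rng.standard_normal(n)
            light = crown_gain[ids] * np.clip(1.0 + crown_speckle[ids] * z, 0.3, 1.8)
            vals = vals * light[None, :]
        else:
            speckle = entry.get("speckle", 0.0)
            if speckle:
                light = np.clip(rng.normal(1.0, speckle, size=n), 0.3, 1.8)
                vals = vals * light[None, :]
        bands[:, sel] = vals
    img = MultibandImage(
        bands=np.clip(np.round(bands), 0, dn_max).astype(np.uint16 if spec.bit_depth > 8 else np.uint8),
        pixel_size_m=spec.pixel_size_m,
        bit_depth=spec.bit_depth,
        year_label=spec.year_label,
    )
    truth = ClassMap(
        labels=labels,
        pixel_size_m=spec.pixel_size_m,
        year_label=spec.year_label,
    )
    shadow = np.zeros(shape, dtype=bool)
    if spec.shadows_on:
        img, shadow = cast_shadows(
            img,
            truth,
            spec.sun_azimuth_deg,
            spec.sun_elevation_deg,
            tree_height_m=spec.tree_height_m,
            shadow_factor=spec.shadow_factor,
            shadow_nir_factor=spec.shadow_nir_factor,
        )
    if spec.saturation_on:
        img = apply_saturation(
            img,
            plateau_dn=spec.saturation_plateau_dn,
            knee_dn=spec.saturation_knee_dn,
            tau_dn=spec.saturation_tau_dn,
        )
    total = spec.height * spec.width
    rows = []
    for i, name in enumerate(surfaces):
        n = int((surf == i).sum())
        rows.append({
            "surface": name,
            "truth_label": spec.radiometry[name]["label"],
            "pixels": n,
            "fraction": n / total,
        })
    book = pd.DataFrame(rows)
    book.attrs["shadow_pixels"] = int(shadow.sum())
    return img, truth, book


def shadow_mask_as_binary(shadow: np.ndarray, spec: SceneSpec) -> BinaryMask:
    return BinaryMask(values=shadow, pixel_size_m=spec.pixel_size_m)
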