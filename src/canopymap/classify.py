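"""Two-stage threshold decision tree separating tree canopy, grassland and
non-vegetation.

Stage I delineates vegetation: a pixel is non-vegetation iff
``NDWI > ndwi_min AND NDVI < ndvi_max`` (water has NDWI > 0; impervious
surfaces and bare soil have low NDVI). Stage II splits vegetation with two
decision nodes: Node 1 re-labels bright pixels (``brightness >
brightness_nonveg_min``) as non-vegetation — some building materials trigger
a deceptively high NDVI but are far brighter than foliage — and Node 2 calls
a pixel tree canopy when it is dark (``brightness < brightness_tree_max``) or
texturally rough (``texture > texture_tree_min``); everything left is
grassland. All inequalities are strict; boundary-equal values fall through to
the next rule.

Thresholds are calibrated per acquisition year. The per-pixel rule set is
exposed as a scikit-learn style estimator (:class:`ThresholdTreeClassifier`)
whose ``fit`` derives *initial* cutoffs from unlabeled reference samples by
two-cluster partitioning; the raster-level functions are thin wrappers.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .types import BinaryMask, ClassMap, GRASS, IndexStack, NONVEG, TREE

FEATURE_NAMES = ("ndvi", "ndwi", "brightness", "texture")


@dataclass
class ThresholdConfig:
    """Year-specific decision thresholds plus sieve and texture settings."""

    year_label: str = "custom"
    ndwi_min: float = 0.0
    ndvi_max: float = -0.05
    brightness_nonveg_min: float = 150_000.0
    brightness_tree_max: float = 50_000.0
    texture_tree_min: float = 50.0
    sieve_min_pixels: int = 9
    connectivity: int = 8
    pixel_size_m: float = 1.0
    texture_window: int = 3
    texture_statistic: str = "contrast"
    texture_levels: int = 32
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in (
            "ndwi_min",
            "ndvi_max",
            "brightness_nonveg_min",
            "brightness_tree_max",
            "texture_tree_min",
        ):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.brightness_tree_max >= self.brightness_nonveg_min:
            raise ValueError(
                "brightness_tree_max must be below brightness_nonveg_min"
            )
        if self.sieve_min_pixels < 1:
            raise ValueError("sieve_min_pixels must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")

    def replace(self, **kwargs) -> "ThresholdConfig":
        return replace(self, **kwargs)


def load_year_config(year: str, path: Optional[str] = None) -> ThresholdConfig:
    """Load the packaged (or a user) YAML threshold file for one year."""
    if path is None:
        ref = importlib.resources.files("canopymap") / "configs" / "thresholds.yaml"
        raw = yaml.safe_load(ref.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    years = raw.get("years", {})
    year = str(year)
    if year not in years:
        raise KeyError(f"year {year!r} not in config (have {sorted(years)})")
    entry = dict(years[year])
    defaults = raw.get("defaults", {})
    # sieve threshold derives from the configured minimum area and pixel size
    from .postprocess import scale_sieve_threshold

    min_area = entry.pop("sieve_min_area_m2", None)
    cfg = ThresholdConfig(
        year_label=year,
        connectivity=int(defaults.get("connectivity", 8)),
        texture_window=int(defaults.get("texture_window", 3)),
        texture_statistic=str(defaults.get("texture_statistic", "contrast")),
        texture_levels=int(defaults.get("texture_levels", 32)),
        **entry,
    )
    if min_area is not None:
        cfg = cfg.replace(
            sieve_min_pixels=scale_sieve_threshold(min_area, cfg.pixel_size_m)
        )
    return cfg


def available_years(path: Optional[str] = None) -> list:
    if path is None:
        ref = importlib.resources.files("canopymap") / "configs" / "thresholds.yaml"
        raw = yaml.safe_load(ref.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    return sorted(raw.get("years", {}))


# ---------------------------------------------------------------------------
# scikit-learn estimator over per-pixel feature vectors


class ThresholdTreeClassifier(BaseEstimator, ClassifierMixin):
    """Fixed-structure two-stage decision tree over (ndvi, ndwi, brightness,
    texture) feature vectors.

    Parameters mirror :class:`ThresholdConfig`. Any threshold left as ``None``
    is proposed during :meth:`fit` by unsupervised two-cluster partitioning of
    the corresponding feature (cluster-boundary midpoint); thresholds given
    explicitly are kept as-is, so a fully specified classifier needs no
    fitting data beyond ``fit(None)``. Proposed cutoffs are *initial*
    estimates intended for manual refinement.

    ``predict`` maps rows to class codes 3 (tree), 2 (non-vegetation) and
    1 (grassland).
    """

    def __init__(
        self,
        ndwi_min: Optional[float] = 0.0,
        ndvi_max: Optional[float] = -0.05,
        brightness_nonveg_min: Optional[float] = 150_000.0,
        brightness_tree_max: Optional[float] = 50_000.0,
        texture_tree_min: Optional[float] = 50.0,
    ):
        self.ndwi_min = ndwi_min
        self.ndvi_max = ndvi_max
        self.brightness_nonveg_min = brightness_nonveg_min
        self.brightness_tree_max = brightness_tree_max
        self.texture_tree_min = texture_tree_min

    _param_to_feature = {
        "ndwi_min": "ndwi",
        "ndvi_max": "ndvi",
        "brightness_nonveg_min": "brightness",
        "brightness_tree_max": "brightness",
        "texture_tree_min": "texture",
    }

    def fit(self, X=None, y=None):
        self.classes_ = np.array([GRASS, NONVEG, TREE])
        resolved = {}
        missing = [p for p, v in self._threshold_params().items() if v is None]
        if missing:
            if X is None:
                raise ValueError(
                    f"thresholds {missing} are unset; fit requires samples"
                )
            table = _as_feature_table(X)
            proposals = propose_thresholds(
                table, sorted({self._param_to_feature[p] for p in missing})
            )
            for p in missing:
                resolved[p] = proposals[self._param_to_feature[p]]
        for p, v in self._threshold_params().items():
            if p not in resolved:
                resolved[p] = float(v)
        self.thresholds_ = resolved
        self.n_features_in_ = 4
        return self

    def _threshold_params(self) -> Dict[str, Optional[float]]:
        return {p: getattr(self, p) for p in self._param_to_feature}

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "thresholds_")
        table = _as_feature_table(X)
        t = self.thresholds_
        ndvi = table["ndvi"].to_numpy(float)
        ndwi = table["ndwi"].to_numpy(float)
        bright = table["brightness"].to_numpy(float)
        texture = table["texture"].to_numpy(float)
        stage1_nonveg = (ndwi > t["ndwi_min"]) & (ndvi < t["ndvi_max"])
        nonveg = stage1_nonveg | (bright > t["brightness_nonveg_min"])
        tree = ~nonveg & (
            (bright < t["brightness_tree_max"]) | (texture > t["texture_tree_min"])
        )
        out = np.full(len(table), GRASS, dtype=np.int64)
        out[nonveg] = NONVEG
        out[tree] = TREE
        return out

    def to_config(self, **kwargs) -> ThresholdConfig:
        check_is_fitted(self, "thresholds_")
        return ThresholdConfig(**self.thresholds_, **kwargs)

    @classmethod
    def from_config(cls, cfg: ThresholdConfig) -> "ThresholdTreeClassifier":
        est = cls(
            ndwi_min=cfg.ndwi_min,
            ndvi_max=cfg.ndvi_max,
            brightness_nonveg_min=cfg.brightness_nonveg_min,
            brightness_tree_max=cfg.brightness_tree_max,
            texture_tree_min=cfg.texture_tree_min,
        )
        return est.fit()


def _as_feature_table(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        missing = [c for c in FEATURE_NAMES if c not in X.columns]
        if missing:
            raise ValueError(f"feature table lacks columns {missing}")
        return X
    arr = check_array(X, ensure_2d=True)
    if arr.shape[1] != len(FEATURE_NAMES):
        raise ValueError(
            f"expected {len(FEATURE_NAMES)} feature columns {FEATURE_NAMES}, "
            f"got {arr.shape[1]}"
        )
    return pd.DataFrame(arr, columns=list(FEATURE_NAMES))


# ---------------------------------------------------------------------------
# threshold initialization


def _two_cluster_cut(values: np.ndarray, feature: str) -> float:
    """Optimal 1-D two-cluster split (minimum within-cluster sum of squares),
    returned as the midpoint between the two cluster boundaries."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size < 2:
        raise ValueError(f"feature {feature!r}: need >= 2 samples")
    if v[0] == v[-1]:
        raise ValueError(f"feature {feature!r}: all samples identical")
    # exhaustive scan over the n-1 sorted split points via prefix sums
    c1 = np.cumsum(v)
    c2 = np.cumsum(v ** 2)
    n = v.size
    k = np.arange(1, n)  # left cluster sizes
    left_ss = c2[k - 1] - c1[k - 1] ** 2 / k
    rs1 = c1[-1] - c1[k - 1]
    rs2 = c2[-1] - c2[k - 1]
    right_ss = rs2 - rs1 ** 2 / (n - k)
    best = int(np.argmin(left_ss + right_ss))
    return float((v[best] + v[best + 1]) / 2.0)


def propose_thresholds(
    samples: pd.DataFrame,
    features: Sequence[str],
    seed: Optional[int] = None,
    n_max: Optional[int] = None,
) -> Dict[str, float]:
    """Initial per-feature cutoffs from two-cluster unsupervised partitioning.

    For each named feature column the sampled values are split into two
    clusters by the exact 1-D minimum within-cluster-variance partition and
    the cutoff is the midpoint between the clusters' facing boundaries. The
    result is an *initial* estimate meant to seed manual refinement.

    ``seed``/``n_max`` optionally subsample large reference tables
    reproducibly; the split itself is deterministic.
    """
    out: Dict[str, float] = {}
    for feature in features:
        if feature not in samples.columns:
            raise ValueError(f"samples lack feature column {feature!r}")
        values = samples[feature].to_numpy(dtype=float)
        values = values[np.isfinite(values)]
        if n_max is not None and values.size > n_max:
            rng = np.random.default_rng(seed)
            values = rng.choice(values, size=n_max, replace=False)
        out[feature] = _two_cluster_cut(values, feature)
    return out


# ---------------------------------------------------------------------------
# raster-level wrappers


def stage1_vegetation_mask(idx: IndexStack, cfg: ThresholdConfig) -> BinaryMask:
    """Stage I: TRUE where vegetation (i.e. NOT (ndwi > min AND ndvi < max))."""
    nonveg = (idx.ndwi > cfg.ndwi_min) & (idx.ndvi < cfg.ndvi_max)
    return BinaryMask(
        values=~nonveg,
        pixel_size_m=idx.pixel_size_m,
        nodata_mask=idx.nodata_mask.copy(),
        geotransform=idx.geotransform,
    )


def stage2_classify(idx: IndexStack, veg: BinaryMask, cfg: ThresholdConfig) -> ClassMap:
    """Stage II Nodes 1-2 applied on top of a Stage I vegetation mask.

    The partition is exhaustive and mutually exclusive: Node 1's OR can
    overturn a Stage I vegetation call but never a non-vegetation one.
    """
    if veg.shape != idx.shape:
        raise ValueError(f"mask shape {veg.shape} != index shape {idx.shape}")
    nonveg = (~veg.values) | (idx.brightness > cfg.brightness_nonveg_min)
    tree = ~nonveg & (
        (idx.brightness < cfg.brightness_tree_max)
        | (idx.texture > cfg.texture_tree_min)
    )
    labels = np.full(idx.shape, GRASS, dtype=np.int64)
    labels[nonveg] = NONVEG
    labels[tree] = TREE
    return ClassMap(
        labels=labels,
        pixel_size_m=idx.pixel_size_m,
        nodata_mask=idx.nodata_mask.copy(),
        geotransform=idx.geotransform,
        year_label=cfg.year_label,
    )
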