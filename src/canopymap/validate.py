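"""Accuracy assessment: stratified grid sampling, confusion matrices,
overall accuracy, and inter-year mask overlap.

The sampling design subdivides a validation tile into a regular grid and
draws samples from every cell, stratified across the classes present in the
cell — spatially balanced in the way a purely random draw is not. Pixels are
the sampling unit; polygon ground truth should be rasterized first.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .postprocess import resample_nearest
from .types import BinaryMask, ClassMap, GRASS, NONVEG, TREE

DEFAULT_LABELS = (GRASS, NONVEG, TREE)


@dataclass
class ConfusionMatrix:
    """K x K count matrix; rows are truth, columns are predictions."""

    counts: np.ndarray
    labels: Tuple[int, ...] = DEFAULT_LABELS
    n_invalid: int = 0  # samples falling on nodata predictions, excluded

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be K x K for K labels")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels), columns=list(self.labels))

    def collapse(self, mapping: dict) -> "ConfusionMatrix":
        """Merge labels (e.g. {1: "veg", 3: "veg", 2: "nonveg"}) into a
        coarser confusion matrix."""
        groups = sorted(set(mapping.values()), key=str)
        gi = {g: i for i, g in enumerate(groups)}
        out = np.zeros((len(groups), len(groups)), dtype=np.int64)
        for i, li in enumerate(self.labels):
            for j, lj in enumerate(self.labels):
                out[gi[mapping[li]], gi[mapping[lj]]] += self.counts[i, j]
        return ConfusionMatrix(out, labels=tuple(groups), n_invalid=self.n_invalid)


#: label groupings for the two headline accuracy figures
VEGETATION_GROUPING = {GRASS: "veg", TREE: "veg", NONVEG: "nonveg"}
TREE_GROUPING = {TREE: "tree", GRASS: "nontree", NONVEG: "nontree"}


def stratified_grid_sample(
    tile_extent: Optional[Tuple[int, int, int, int]],
    grid: Tuple[int, int],
    truth: ClassMap,
    per_cell: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw up to ``per_cell`` validation pixels from every grid cell.

    ``tile_extent`` is ``(row0, col0, height, width)`` in pixel coordinates
    (``None`` = the full map); ``grid`` is ``(n_rows, n_cols)`` of cells.
    Within a cell, draws cycle over the classes present so each is
    represented before any is repeated. Reproducible given ``seed``.
    """
    if tile_extent is None:
        tile_extent = (0, 0, truth.shape[0], truth.shape[1])
    r0, c0, th, tw = tile_extent
    gy, gx = grid
    if th < gy or tw < gx:
        raise ValueError("grid cells would be smaller than one pixel")
    valid = ~truth.nodata_mask
    if not valid[r0 : r0 + th, c0 : c0 + tw].any():
        raise ValueError("truth has no valid pixels in the tile")
    rng = np.random.default_rng(seed)
    records = []
    row_edges = np.linspace(r0, r0 + th, gy + 1).round().astype(int)
    col_edges = np.linspace(c0, c0 + tw, gx + 1).round().astype(int)
    for gi in range(gy):
        for gj in range(gx):
            rows = slice(row_edges[gi], row_edges[gi + 1])
            cols = slice(col_edges[gj], col_edges[gj + 1])
            sub_valid = valid[rows, cols]
            rr, cc = np.nonzero(sub_valid)
            if rr.size == 0:
                continue
            lab = truth.labels[rows, cols][rr, cc]
            classes = np.unique(lab)
            rng.shuffle(classes)
            pools = {}
            for cl in classes:
                members = np.nonzero(lab == cl)[0]
                pools[cl] = list(rng.permutation(members))
            picked = []
            while len(picked) < per_cell:
                progressed = False
                for cl in classes:
                    if len(picked) >= per_cell:
                        break
                    if pools[cl]:
                        picked.append(pools[cl].pop())
                        progressed = True
                if not progressed:
                    break
            for p in picked:
                records.append({
                    "row": int(rows.start + rr[p]),
                    "col": int(cols.start + cc[p]),
                    "truth": int(lab[p]),
                })
    return pd.DataFrame(records, columns=["row", "col", "truth"])


def confusion(
    pred: ClassMap,
    samples: pd.DataFrame,
    labels: Sequence[int] = DEFAULT_LABELS,
) -> ConfusionMatrix:
    """Tally (truth, predicted) pairs at the sampled pixels.

    Samples outside the prediction extent raise (they are reported, never
    silently dropped); samples on nodata predictions are excluded and
    counted in ``n_invalid``.
    """
    rows = samples["row"].to_numpy(int)
    cols = samples["col"].to_numpy(int)
    h, w = pred.shape
    out = (rows < 0) | (rows >= h) | (cols < 0) | (cols >= w)
    if out.any():
        raise ValueError(
            f"{int(out.sum())} of {len(samples)} samples fall outside the "
            f"prediction extent {pred.shape}"
        )
    invalid = pred.nodata_mask[rows, cols]
    truth = samples["truth"].to_numpy(int)[~invalid]
    predicted = pred.labels[rows[~invalid], cols[~invalid]]
    labels = tuple(labels)
    li = {l: i for i, l in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for t, p in zip(truth, predicted):
        counts[li[int(t)], li[int(p)]] += 1
    return ConfusionMatrix(counts, labels=labels, n_invalid=int(invalid.sum()))


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Trace over total; in [0, 1]."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total)


def vegetation_accuracy(cm: ConfusionMatrix) -> float:
    """Binary vegetation-vs-non-vegetation overall accuracy."""
    return overall_accuracy(cm.collapse(VEGETATION_GROUPING))


def tree_accuracy(cm: ConfusionMatrix, binary: bool = True) -> float:
    """Tree-detection overall accuracy: binary tree-vs-nontree by default,
    or the full three-class accuracy with ``binary=False``."""
    if binary:
        return overall_accuracy(cm.collapse(TREE_GROUPING))
    return overall_accuracy(cm)


def tree_grass_accuracy(cm: ConfusionMatrix) -> float:
    """Tree/grass separation accuracy over samples whose truth is vegetated:
    correct iff a true tree sample is predicted tree and a true grass sample
    predicted grass (a non-vegetation prediction on either counts as an
    error)."""
    li = {l: i for i, l in enumerate(cm.labels)}
    veg_rows = [li[GRASS], li[TREE]]
    total = int(cm.counts[veg_rows, :].sum())
    if total == 0:
        raise ValueError("no vegetated truth samples")
    correct = int(cm.counts[li[GRASS], li[GRASS]] + cm.counts[li[TREE], li[TREE]])
    return correct / total


def mask_overlap(mask_a: BinaryMask, mask_b: BinaryMask) -> float:
    """Percentage of the first mask's TRUE pixels also TRUE in the second:
    ``|A intersect B| / |A| * 100``. Asymmetric by design — A is the mask
    under scrutiny, B the reference."""
    a, b = mask_a.values, mask_b.values
    if a.shape != b.shape:
        b = resample_nearest(b, a.shape)
    n_a = int(a.sum())
    if n_a == 0:
        raise ValueError("first mask has no TRUE pixels")
    return 100.0 * int((a & b).sum()) / n_a


def jaccard_overlap(mask_a: BinaryMask, mask_b: BinaryMask) -> float:
    """Symmetric alternative: |A intersect B| / |A union B| * 100."""
    a, b = mask_a.values, mask_b.values
    if a.shape != b.shape:
        b = resample_nearest(b, a.shape)
    union = int((a | b).sum())
    if union == 0:
        raise ValueError("both masks are empty")
    return 100.0 * int((a & b).sum()) / union
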