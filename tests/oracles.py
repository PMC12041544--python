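"""Independent brute-force reference implementations used only by tests.

Each oracle is written as plain Python enumeration so it shares no code path
with the package implementation it checks.
"""

import numpy as np

OFFSETS_8 = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)]


def quantize_ref(values, bit_depth, levels):
    out = np.empty(values.shape, dtype=int)
    for idx in np.ndindex(values.shape):
        q = int(values[idx] * levels // (2 ** bit_depth))
        out[idx] = min(max(q, 0), levels - 1)
    return out


def texture_oracle(nir, bit_depth=8, window=3, statistic="contrast", levels=32):
    """Per-pixel co-occurrence statistic by exhaustive pair enumeration."""
    q = quantize_ref(np.asarray(nir), bit_depth, levels)
    r = window // 2
    qp = np.pad(q, r, mode="reflect")
    h, w = q.shape
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            win = qp[i : i + window, j : j + window]
            pairs = []
            for dy, dx in OFFSETS_8:
                for y in range(window):
                    for x in range(window):
                        y2, x2 = y + dy, x + dx
                        if 0 <= y2 < window and 0 <= x2 < window:
                            pairs.append((win[y, x], win[y2, x2]))
            vals = np.array(pairs, dtype=float)
            a, b = vals[:, 0], vals[:, 1]
            if statistic == "contrast":
                out[i, j] = np.mean((a - b) ** 2)
            elif statistic == "dissimilarity":
                out[i, j] = np.mean(np.abs(a - b))
            elif statistic == "variance":
                out[i, j] = np.mean((a - a.mean()) ** 2)
            else:
                raise ValueError(statistic)
    return out


def classify_oracle(ndvi, ndwi, brightness, texture, cfg):
    """Per-pixel evaluation of the two-stage threshold rules."""
    h, w = np.asarray(ndvi).shape
    out = np.zeros((h, w), dtype=int)
    for i in range(h):
        for j in range(w):
            stage1_nonveg = (ndwi[i, j] > cfg.ndwi_min) and (ndvi[i, j] < cfg.ndvi_max)
            if stage1_nonveg or brightness[i, j] > cfg.brightness_nonveg_min:
                out[i, j] = 2
            elif (brightness[i, j] < cfg.brightness_tree_max) or (
                texture[i, j] > cfg.texture_tree_min
            ):
                out[i, j] = 3
            else:
                out[i, j] = 1
    return out


def sieve_oracle(veg_mask, min_pixels, connectivity):
    """Flood-fill component enumeration over non-vegetation (FALSE) pixels."""
    veg = np.array(veg_mask, dtype=bool)
    h, w = veg.shape
    if connectivity == 4:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        steps = OFFSETS_8
    seen = np.zeros((h, w), dtype=bool)
    out = veg.copy()
    for i in range(h):
        for j in range(w):
            if veg[i, j] or seen[i, j]:
                continue
            stack, comp = [(i, j)], []
            seen[i, j] = True
            while stack:
                y, x = stack.pop()
                comp.append((y, x))
                for dy, dx in steps:
                    y2, x2 = y + dy, x + dx
                    if 0 <= y2 < h and 0 <= x2 < w and not veg[y2, x2] and not seen[y2, x2]:
                        seen[y2, x2] = True
                        stack.append((y2, x2))
            if len(comp) < min_pixels:
                for y, x in comp:
                    out[y, x] = True
    return out
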