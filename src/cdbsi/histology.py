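"""Histology density maps and MRI-histology grid correlation.

Binary positive-stain masks (nuclei from H&E, collagen/muscle from trichrome,
already classified and registered upstream) are converted to windowed density
maps — the percentage of positive pixels per non-overlapping window — then
block-downsampled onto coarser physical grids and compared with MR parameter
maps by Pearson correlation of per-box means over a fixed physical tiling
(2.5 x 2.5 mm boxes by default, matching the in vivo diffusion resolution).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StainMask",
    "DensityMap",
    "density_map",
    "downsample_map",
    "grid_correlation",
    "classify_trichrome_hsv",
]

STAIN_LABELS = ("nuclei", "collagen", "muscle")


@dataclass(frozen=True)
class StainMask:
    """Binary positive-stain pixel grid with physical pixel size."""

    pixels: np.ndarray  # 2D, values {0, 1} (0/255 accepted and normalized)
    pixel_size_um: float = 0.46  # 20x scan
    stain: str = "nuclei"

    def __post_init__(self):
        p = np.asarray(self.pixels)
        if p.ndim != 2 or p.size == 0:
            raise ValueError("mask must be a non-empty 2D array")
        vals = np.unique(p)
        if not np.all(np.isin(vals, (0, 1, 255))):
            raise ValueError("mask values must be binary (0/1 or 0/255)")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be > 0")
        if self.stain not in STAIN_LABELS:
            raise ValueError(f"stain must be one of {STAIN_LABELS}")
        object.__setattr__(self, "pixels", (p > 0).astype(np.uint8))


@dataclass
class DensityMap:
    """Positive-stain percentage per grid cell, with cell size and pixel weights.

    ``weights`` holds the number of source pixels per cell so that chained
    block means stay area-weighted at partial edge cells.
    """

    values: np.ndarray  # 2D, percent in [0, 100]
    cell_size: float  # physical cell edge (same unit as the source pixel size)
    weights: np.ndarray | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("values must be 2D")
        if np.any((v < -1e-9) | (v > 100 + 1e-9)):
            raise ValueError("density values must lie in [0, 100]")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        self.values = v
        if self.weights is None:
            self.weights = np.ones_like(v)


def _block_sums(arr: np.ndarray, window: int) -> np.ndarray:
    """Sums over a non-overlapping window tiling; edge blocks are partial."""
    rows = np.add.reduceat(arr, np.arange(0, arr.shape[0], window), axis=0)
    return np.add.reduceat(rows, np.arange(0, arr.shape[1], window), axis=1)


def density_map(mask: StainMask | np.ndarray, window: int = 50,
                pixel_size: float = 1.0) -> DensityMap:
    """Windowed positive-stain density: % positive pixels per window.

    The mask is tiled with non-overlapping ``window x window`` blocks anchored
    at the origin; each cell is 100 * positive / pixel-count, with edge cells
    using their actual (partial) pixel count.
    """
    if isinstance(mask, StainMask):
        pix, pixel_size = mask.pixels, mask.pixel_size_um
    else:
        pix = np.asarray(mask)
        if pix.ndim != 2 or pix.size == 0:
            raise ValueError("mask must be a non-empty 2D array")
        pix = (pix > 0).astype(np.uint8)
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > pix.shape[0] and window > pix.shape[1]:
        raise ValueError("window larger than both mask dimensions")
    pos = _block_sums(pix.astype(float), window)
    counts = _block_sums(np.ones_like(pix, dtype=float), window)
    return DensityMap(100.0 * pos / counts, cell_size=window * pixel_size,
                      weights=counts)


def downsample_map(dmap: DensityMap, target_cell_size: float) -> DensityMap:
    """Block-mean a density map onto a coarser grid.

    Each source cell is assigned to the target cell containing its center; the
    target value is the pixel-count-weighted mean, which preserves the total
    positive area exactly for integer downsampling factors.
    """
    if target_cell_size < dmap.cell_size:
        raise ValueError("target cell size must be >= source cell size")
    factor = target_cell_size / dmap.cell_size
    if abs(factor - 1.0) < 1e-12:
        return DensityMap(dmap.values.copy(), dmap.cell_size,
                          dmap.weights.copy())
    nr, nc = dmap.values.shape
    ri = np.floor((np.arange(nr) + 0.5) / factor).astype(int)
    ci = np.floor((np.arange(nc) + 0.5) / factor).astype(int)
    out_shape = (ri.max() + 1, ci.max() + 1)
    wsum = np.zeros(out_shape)
    vsum = np.zeros(out_shape)
    np.add.at(wsum, (ri[:, None], ci[None, :]), dmap.weights)
    np.add.at(vsum, (ri[:, None], ci[None, :]), dmap.weights * dmap.values)
    with np.errstate(invalid="ignore"):
        vals = np.where(wsum > 0, vsum / np.maximum(wsum, 1e-300), 0.0)
    return DensityMap(vals, target_cell_size, weights=wsum)


def _box_means(values: np.ndarray, cell_size: float, box: float,
               frame_shape_boxes: tuple[int, int],
               weights: np.ndarray | None = None):
    """Per-box weighted means and coverage weights on a fixed physical tiling."""
    nr, nc = values.shape
    ri = np.floor((np.arange(nr) + 0.5) * cell_size / box).astype(int)
    ci = np.floor((np.arange(nc) + 0.5) * cell_size / box).astype(int)
    nb = frame_shape_boxes
    w = np.ones_like(values) if weights is None else weights
    wsum = np.zeros(nb)
    vsum = np.zeros(nb)
    ok = (ri[:, None] < nb[0]) & (ci[None, :] < nb[1])
    rr = np.broadcast_to(ri[:, None], values.shape)[ok]
    cc = np.broadcast_to(ci[None, :], values.shape)[ok]
    np.add.at(wsum, (rr, cc), w[ok])
    np.add.at(vsum, (rr, cc), (w * values)[ok])
    with np.errstate(invalid="ignore"):
        means = np.where(wsum > 0, vsum / np.maximum(wsum, 1e-300), np.nan)
    return means, wsum


def grid_correlation(
    map_a,
    map_b,
    box: float = 2.5,
    contour: np.ndarray | None = None,
    min_coverage: float = 0.5,
):
    """Pearson correlation of per-box means of two co-registered maps.

    Both maps (``DensityMap`` or ``(values, cell_size)`` pairs) must live on
    the same physical frame anchored at the origin.  The frame is tiled with
    ``box x box`` physical boxes; boxes whose contour coverage (fraction of
    map-A cells inside ``contour``, a boolean array on map A's grid) is below
    ``min_coverage`` are dropped, as are boxes not covered by both maps.
    Returns ``(r, p, n_boxes, table)`` with a per-box DataFrame of paired
    means; the p-value is two-sided.
    """
    def unpack(m):
        if isinstance(m, DensityMap):
            return m.values, m.cell_size, m.weights
        values, cell = m
        return np.asarray(values, dtype=float), float(cell), None

    va, ca, wa = unpack(map_a)
    vb, cb, wb = unpack(map_b)
    extent = (max(va.shape[0] * ca, vb.shape[0] * cb),
              max(va.shape[1] * ca, vb.shape[1] * cb))
    nb = (int(np.ceil(extent[0] / box)), int(np.ceil(extent[1] / box)))

    mean_a, cover_a = _box_means(va, ca, box, nb, wa)
    mean_b, _ = _box_means(vb, cb, box, nb, wb)

    usable = np.isfinite(mean_a) & np.isfinite(mean_b)
    if contour is not None:
        contour = np.asarray(contour).astype(bool)
        if contour.shape != va.shape:
            raise ValueError("contour must be on map A's grid")
        in_contour, total = _box_means(contour.astype(float), ca, box, nb)
        coverage = np.where(np.isfinite(in_contour), in_contour, 0.0)
        usable &= coverage >= min_coverage

    idx = np.argwhere(usable)
    if len(idx) < 3:
        raise ValueError(f"only {len(idx)} usable grid boxes (< 3)")
    a = mean_a[usable]
    b = mean_b[usable]
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance in box means: correlation undefined")
    r, p = stats.pearsonr(a, b)
    table = pd.DataFrame(
        {"box_row": idx[:, 0], "box_col": idx[:, 1], "mean_a": a, "mean_b": b}
    )
    return float(r), float(p), len(idx), table


def classify_trichrome_hsv(
    rgb: np.ndarray,
    stain: str = "collagen",
    saturation_min: float = 0.2,
    value_min: float = 0.2,
) -> np.ndarray:
    """Crude HSV-threshold segmentation of trichrome blue (collagen) / scarlet
    (muscle).

    Convenience helper only — a simple chromatic threshold, NOT equivalent to a
    trained tissue classifier; intended for quick looks at trichrome rasters.
    """
    from matplotlib.colors import rgb_to_hsv  # lazy: only needed here

    arr = np.asarray(rgb, dtype=float)
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise ValueError("expected an RGB image")
    if arr.max() > 1.0:
        arr = arr / 255.0
    hsv = rgb_to_hsv(arr[..., :3])
    h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    if stain == "collagen":  # blue hues
        hue_ok = (h >= 0.5) & (h <= 0.75)
    elif stain == "muscle":  # scarlet/red hues
        hue_ok = (h <= 0.06) | (h >= 0.92)
    else:
        raise ValueError("stain must be 'collagen' or 'muscle'")
    return (hue_ok & (s >= saturation_min) & (v >= value_min)).astype(np.uint8)
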