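"""Marker thresholding and the mask arithmetic defining mismatch categories.

Each hypoxia-marker channel is binarised inside the tumour ROI, either at a
global preset intensity or by Otsu's method on the 8-bit ROI-restricted
histogram.  The two marker masks are then combined with set arithmetic into
the three mismatch categories:

* ``reoxygenated`` — baseline marker only (CCI-103F minus pimonidazole),
* ``new_hypoxia`` — post-treatment marker only (pimonidazole minus CCI-103F),
* ``no_change``   — the overlap (CCI-103F AND pimonidazole).

Positivity is ``intensity >= threshold`` throughout; this convention is fixed
and documented because tool conventions vary.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage


class Category(enum.IntEnum):
    """Label codes of the per-pixel category map."""

    OUTSIDE_ROI = 0
    BACKGROUND = 1
    REOXYGENATED = 2
    NEW_HYPOXIA = 3
    NO_CHANGE = 4


@dataclass
class MarkerMask:
    """A binarised marker channel restricted to the ROI."""

    mask: np.ndarray
    marker: str
    method: str  # "preset" | "otsu"
    threshold_value: float
    roi_area_px: int


@dataclass
class CategoryMap:
    """Per-pixel partition into mismatch categories.

    ``labels`` holds :class:`Category` codes; the categories partition the
    image and ``reoxygenated | new_hypoxia | no_change`` equals
    ``(CCI union Pimo) intersect ROI`` by construction.
    """

    labels: np.ndarray
    cci: MarkerMask
    pimo: MarkerMask

    def mask(self, category: Category) -> np.ndarray:
        return self.labels == int(category)


def preset_threshold(
    channel: np.ndarray, roi: np.ndarray, threshold_value: float, marker: str = ""
) -> MarkerMask:
    """Binarise a channel at a global preset intensity inside the ROI.

    A pixel is positive iff its intensity is >= ``threshold_value`` and it
    lies inside the ROI.
    """
    roi = roi.astype(bool)
    n_roi = int(roi.sum())
    if n_roi == 0:
        raise ValueError("empty ROI: nothing to threshold")
    mask = (channel >= threshold_value) & roi
    return MarkerMask(
        mask=mask,
        marker=marker,
        method="preset",
        threshold_value=float(threshold_value),
        roi_area_px=n_roi,
    )


def otsu_threshold(channel: np.ndarray, roi: np.ndarray, marker: str = "") -> MarkerMask:
    """Binarise an 8-bit channel by Otsu's method on the ROI-restricted histogram.

    The threshold t maximises the between-class variance of the classes
    ``{v < t}`` and ``{v >= t}`` over the 256-bin histogram of ROI pixels;
    ties are broken toward the lower threshold.  Positivity is
    ``intensity >= t``.  A constant ROI has no threshold and raises.
    """
    roi = roi.astype(bool)
    n_roi = int(roi.sum())
    if n_roi == 0:
        raise ValueError("empty ROI: nothing to threshold")
    vals = channel[roi]
    if vals.min() < 0 or vals.max() > 255:
        raise ValueError(
            "otsu_threshold expects an 8-bit channel (values in [0, 255]); "
            "convert with to_8bit first"
        )
    if vals.min() == vals.max():
        raise ValueError("no threshold exists: ROI intensities are constant")
    counts = np.bincount(vals.astype(np.int64).ravel(), minlength=256).astype(np.float64)
    levels = np.arange(256, dtype=np.float64)
    # class 0 = {v < t}, class 1 = {v >= t} for candidate thresholds t=1..255
    w0 = np.cumsum(counts)[:-1]  # weight of class 0 at t = 1..255
    w1 = n_roi - w0
    csum = np.cumsum(counts * levels)[:-1]
    total = float((counts * levels).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = csum / w0
        mu1 = (total - csum) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b[(w0 == 0) | (w1 == 0)] = -np.inf
    t = int(np.argmax(sigma_b)) + 1  # argmax takes the first (lowest) maximiser
    mask = (channel >= t) & roi
    return MarkerMask(
        mask=mask, marker=marker, method="otsu", threshold_value=float(t), roi_area_px=n_roi
    )


def classify_categories(
    cci: MarkerMask,
    pimo: MarkerMask,
    roi: np.ndarray,
    min_object_px: int = 0,
    fill_holes: bool = False,
) -> CategoryMap:
    """Combine the two marker masks into the three mismatch categories.

    ``reoxygenated = CCI \\ Pimo``, ``new_hypoxia = Pimo \\ CCI``,
    ``no_change = CCI & Pimo``; the ROI remainder is background.  The optional
    small-object and hole-fill post-filters (applied to each marker mask
    before the arithmetic) default to off, preserving the raw arithmetic.
    """
    roi = roi.astype(bool)
    if cci.mask.shape != pimo.mask.shape or cci.mask.shape != roi.shape:
        raise ValueError(
            f"shape mismatch: cci {cci.mask.shape}, pimo {pimo.mask.shape}, roi {roi.shape}"
        )
    a = cci.mask & roi
    b = pimo.mask & roi
    if fill_holes:
        a = ndimage.binary_fill_holes(a) & roi
        b = ndimage.binary_fill_holes(b) & roi
    if min_object_px > 0:
        a = _remove_small(a, min_object_px)
        b = _remove_small(b, min_object_px)
    labels = np.full(roi.shape, int(Category.OUTSIDE_ROI), dtype=np.uint8)
    labels[roi] = int(Category.BACKGROUND)
    labels[a & ~b] = int(Category.REOXYGENATED)
    labels[b & ~a] = int(Category.NEW_HYPOXIA)
    labels[a & b] = int(Category.NO_CHANGE)
    return CategoryMap(labels=labels, cci=cci, pimo=pimo)


def _remove_small(mask: np.ndarray, min_px: int) -> np.ndarray:
    lab, n = ndimage.label(mask)
    if n == 0:
        return mask
    sizes = ndimage.sum_labels(np.ones_like(mask, dtype=np.int64), lab, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= min_px) + 1
    return np.isin(lab, keep)


def percent_area(mask: np.ndarray | MarkerMask, roi: np.ndarray) -> float:
    """Percent of ROI area covered by a mask: ``100 * |mask & ROI| / |ROI|``."""
    roi = roi.astype(bool)
    n_roi = int(roi.sum())
    if n_roi == 0:
        raise ValueError("empty ROI")
    m = mask.mask if isinstance(mask, MarkerMask) else mask
    return 100.0 * float((m.astype(bool) & roi).sum()) / n_roi


def integrated_density(channel: np.ndarray, mask: np.ndarray) -> float:
    """Sum of channel intensities over mask pixels (area x mean intensity)."""
    m = mask.mask if isinstance(mask, MarkerMask) else mask
    if m.shape != channel.shape:
        raise ValueError(f"shape mismatch: channel {channel.shape}, mask {m.shape}")
    return float(channel[m.astype(bool)].sum())


def category_table(cmap: CategoryMap) -> pd.DataFrame:
    """Per-category pixel counts and percent areas (of ROI) as a tidy table."""
    roi = cmap.labels != int(Category.OUTSIDE_ROI)
    n_roi = int(roi.sum())
    rows = []
    for cat in (Category.BACKGROUND, Category.REOXYGENATED, Category.NEW_HYPOXIA, Category.NO_CHANGE):
        n = int((cmap.labels == int(cat)).sum())
        rows.append(
            {
                "category": cat.name.lower(),
                "pixels": n,
                "percent_of_roi": 100.0 * n / n_roi if n_roi else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def write_category_map(cmap: CategoryMap, path: str | Path) -> None:
    """Export the label raster as a single-page palette-style TIFF."""
    tifffile.imwrite(Path(path), cmap.labels.astype(np.uint8))
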