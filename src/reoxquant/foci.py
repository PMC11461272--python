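"""Phospho-ATM foci scoring stratified by baseline-hypoxia (CCI-103F) status.

The sampling scheme mirrors the study design: several regions enriched for
the reoxygenated category are chosen at random from a section's category map,
each region contributes multiple high-power fields, and a minimum number of
cells is scored per field.  Within a field, nuclei are segmented from the
counterstain channel (Otsu + hole filling + watershed splitting of touching
nuclei), punctate foci are counted per nucleus with Laplacian-of-Gaussian
blob detection, and each cell is classified by foci burden (0 / 1-5 / >5,
where ">5" is read strictly as >= 6) and by CCI-103F status (majority-pixel
rule).  Percentages are reported per stratum, both pooled over retained cells
and as per-field means, with fields under the cell minimum flagged and
excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import blob_log, peak_local_max
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed

FociClass = Literal["none", "low", "high"]


@dataclass
class FieldSpec:
    """One high-power field inside a scored region."""

    region_id: int
    field_id: int
    bbox: tuple[int, int, int, int]  # (row0, col0, row1, col1), half-open
    magnification: str = "63x"


@dataclass
class CellFociScore:
    """Per-nucleus foci count and classification."""

    nucleus_id: int
    centroid: tuple[float, float]
    area_px: int
    cci_status: Literal["positive", "negative"]
    foci_count: int
    foci_class: FociClass
    region_id: int | None = None
    field_id: int | None = None


@dataclass
class FociReport:
    """Stratified foci-burden percentages with per-field/per-region breakdowns.

    ``per_stratum`` is keyed by CCI-103F status and holds, for each stratum
    that actually contains cells, the retained-cell count and the pooled
    percentages of cells with any foci and with >5 foci; ``per_stratum`` omits
    empty strata rather than reporting 0%.  ``per_field_means`` carries the
    alternative aggregation (mean of per-field percentages).
    """

    per_stratum: dict[str, dict[str, float]]
    per_field: pd.DataFrame
    per_region: pd.DataFrame
    per_field_means: dict[str, dict[str, float]]
    qc_flags: list[str] = field(default_factory=list)


def select_reoxygenated_regions(
    category_map,
    n_regions: int = 6,
    region_size_px: int = 64,
    seed: int = 0,
    min_reox_fraction: float = 0.2,
) -> list[FieldSpec]:
    """Randomly choose non-overlapping regions enriched for reoxygenation.

    The section is tiled into non-overlapping ``region_size_px`` windows; a
    window qualifies when the reoxygenated category covers more than
    ``min_reox_fraction`` of its ROI pixels.  ``n_regions`` windows are drawn
    uniformly without replacement, deterministically under ``seed``.
    """
    from .masks import Category

    labels = category_map.labels
    h, w = labels.shape
    candidates: list[tuple[int, int, int, int]] = []
    for r0 in range(0, h - region_size_px + 1, region_size_px):
        for c0 in range(0, w - region_size_px + 1, region_size_px):
            win = labels[r0 : r0 + region_size_px, c0 : c0 + region_size_px]
            roi_px = int((win != int(Category.OUTSIDE_ROI)).sum())
            if roi_px == 0:
                continue
            reox_px = int((win == int(Category.REOXYGENATED)).sum())
            if reox_px / roi_px > min_reox_fraction:
                candidates.append((r0, c0, r0 + region_size_px, c0 + region_size_px))
    if len(candidates) < n_regions:
        raise ValueError(
            f"insufficient qualifying regions: found {len(candidates)}, "
            f"need {n_regions} (min reoxygenated fraction {min_reox_fraction})"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(candidates), size=n_regions, replace=False)
    return [
        FieldSpec(region_id=i + 1, field_id=0, bbox=candidates[int(j)])
        for i, j in enumerate(sorted(chosen))
    ]


def segment_nuclei(
    nuclei_channel: np.ndarray,
    fieldspec: FieldSpec | None = None,
    min_area_px: int = 30,
) -> np.ndarray:
    """Segment nuclei from the counterstain channel.

    Otsu thresholding, hole filling, then a distance-transform-seeded
    watershed to split touching nuclei; components below ``min_area_px`` are
    dropped.  A blank (constant) field yields zero labels rather than an
    error.  Returns a labelled image the size of the field (or whole channel).
    """
    img = nuclei_channel
    if fieldspec is not None:
        r0, c0, r1, c1 = fieldspec.bbox
        img = img[r0:r1, c0:c1]
    if img.size == 0 or img.min() == img.max():
        return np.zeros(img.shape, dtype=np.int32)
    t = threshold_otsu(img)
    binary = ndimage.binary_fill_holes(img > t)
    if not binary.any():
        return np.zeros(img.shape, dtype=np.int32)
    dist = ndimage.distance_transform_edt(binary)
    min_sep = max(3, int(np.sqrt(min_area_px)))
    peaks = peak_local_max(dist, min_distance=min_sep, labels=binary, exclude_border=False)
    markers = np.zeros(img.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        labels, _ = ndimage.label(binary)
    else:
        labels = watershed(-dist, markers, mask=binary)
    # drop fragments below the minimum area and relabel densely
    out = np.zeros(img.shape, dtype=np.int32)
    nxt = 1
    for lab in range(1, labels.max() + 1):
        m = labels == lab
        if int(m.sum()) >= min_area_px:
            out[m] = nxt
            nxt += 1
    return out


def count_foci(
    patm_channel: np.ndarray,
    nucleus_mask: np.ndarray,
    min_radius_px: float = 1.0,
    max_radius_px: float = 3.5,
    min_prominence: float = 0.08,
    intensity_max: float = 65535.0,
) -> int:
    """Count punctate foci inside one nucleus.

    Laplacian-of-Gaussian blob detection over the given radius range on the
    intensity-normalised channel; maxima whose scale-normalised response falls
    below ``min_prominence`` (relative to ``intensity_max``) are rejected, and
    only blobs whose centre lies inside the nucleus mask are counted.
    Deterministic; foci dimmer than the prominence threshold are not counted.
    """
    if not nucleus_mask.any():
        raise ValueError("nucleus mask is empty")
    rows, cols = np.nonzero(nucleus_mask)
    pad = int(np.ceil(3 * max_radius_px))
    r0 = max(rows.min() - pad, 0)
    r1 = min(rows.max() + pad + 1, patm_channel.shape[0])
    c0 = max(cols.min() - pad, 0)
    c1 = min(cols.max() + pad + 1, patm_channel.shape[1])
    crop = patm_channel[r0:r1, c0:c1].astype(np.float64) / intensity_max
    mask_crop = nucleus_mask[r0:r1, c0:c1]
    sqrt2 = np.sqrt(2.0)
    blobs = blob_log(
        crop,
        min_sigma=min_radius_px / sqrt2,
        max_sigma=max_radius_px / sqrt2,
        num_sigma=8,
        threshold=min_prominence,
        overlap=0.5,
    )
    count = 0
    for br, bc, _sigma in blobs:
        rr = int(round(br))
        cc = int(round(bc))
        if 0 <= rr < mask_crop.shape[0] and 0 <= cc < mask_crop.shape[1] and mask_crop[rr, cc]:
            count += 1
    return count


def classify_count(count: int) -> FociClass:
    """Map a foci count to its burden class; '>5 foci' is strictly >= 6."""
    if count == 0:
        return "none"
    return "high" if count >= 6 else "low"


def score_cells(
    nuclei_labels: np.ndarray,
    foci_counts: Sequence[int] | dict[int, int],
    cci_mask: np.ndarray,
    cci_majority: float = 0.5,
    region_id: int | None = None,
    field_id: int | None = None,
) -> list[CellFociScore]:
    """Classify every segmented nucleus by foci burden and CCI-103F status.

    A nucleus is CCI-positive when at least ``cci_majority`` of its pixels
    fall inside the CCI-103F mask.  ``foci_counts`` is indexed by nucleus
    label (a sequence aligned with labels 1..n, or a dict keyed by label).
    """
    n = int(nuclei_labels.max())
    if isinstance(foci_counts, dict):
        counts = {int(k): int(v) for k, v in foci_counts.items()}
    else:
        if len(foci_counts) != n:
            raise ValueError(
                f"got {len(foci_counts)} foci counts for {n} nuclei labels"
            )
        counts = {lab: int(foci_counts[lab - 1]) for lab in range(1, n + 1)}
    missing = set(range(1, n + 1)) - set(counts)
    if missing:
        raise ValueError(f"missing foci counts for nucleus labels {sorted(missing)}")
    cci = cci_mask.astype(bool)
    cells: list[CellFociScore] = []
    com = ndimage.center_of_mass(
        np.ones_like(nuclei_labels), nuclei_labels, index=range(1, n + 1)
    )
    for lab in range(1, n + 1):
        m = nuclei_labels == lab
        area = int(m.sum())
        frac_in = float((m & cci).sum()) / area
        k = counts[lab]
        cells.append(
            CellFociScore(
                nucleus_id=lab,
                centroid=tuple(float(x) for x in com[lab - 1]),
                area_px=area,
                cci_status="positive" if frac_in >= cci_majority else "negative",
                foci_count=k,
                foci_class=classify_count(k),
                region_id=region_id,
                field_id=field_id,
            )
        )
    return cells


def cells_to_frame(cells: Sequence[CellFociScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "nucleus_id": c.nucleus_id,
                "centroid_row": c.centroid[0],
                "centroid_col": c.centroid[1],
                "area_px": c.area_px,
                "cci_status": c.cci_status,
                "foci_count": c.foci_count,
                "foci_class": c.foci_class,
                "region_id": c.region_id,
                "field_id": c.field_id,
            }
            for c in cells
        ]
    )


def aggregate_foci(
    cells: Sequence[CellFociScore],
    min_cells_per_field: int = 50,
    min_fields_per_region: int = 5,
) -> FociReport:
    """Aggregate per-cell scores into stratified percentages.

    Fields with fewer than ``min_cells_per_field`` cells are flagged and
    excluded from the percentages (the quality-control mirror of excluding
    artefact regions); regions retaining fewer than ``min_fields_per_region``
    fields are flagged but their cells are kept.  Percentages are computed per
    CCI-103F stratum over retained cells, and additionally as means of
    per-field percentages.  A stratum with no cells is reported as absent,
    not as 0%.
    """
    df = cells_to_frame(cells)
    if df.empty:
        raise ValueError("no cells to aggregate")
    qc: list[str] = []
    df["_fkey"] = list(zip(df["region_id"], df["field_id"]))
    field_sizes = df.groupby("_fkey").size()
    bad_fields = [k for k, n in field_sizes.items() if n < min_cells_per_field]
    for k in bad_fields:
        qc.append(f"field region={k[0]} field={k[1]}: {field_sizes[k]} cells < {min_cells_per_field}, excluded")
    kept = df[~df["_fkey"].isin(bad_fields)].copy()
    if kept.empty:
        raise ValueError(
            f"all {len(field_sizes)} fields excluded by the {min_cells_per_field}-cell minimum"
        )
    region_fields = kept.groupby("region_id")["field_id"].nunique()
    for rid, nf in region_fields.items():
        if nf < min_fields_per_region:
            qc.append(f"region {rid}: only {nf} fields retained (< {min_fields_per_region})")

    kept["any_foci"] = kept["foci_count"] > 0
    kept["high_foci"] = kept["foci_class"] == "high"

    def _pct(sub: pd.DataFrame) -> dict[str, float]:
        n = len(sub)
        return {
            "n_cells": float(n),
            "pct_any_foci": 100.0 * float(sub["any_foci"].sum()) / n,
            "pct_high_foci": 100.0 * float(sub["high_foci"].sum()) / n,
        }

    per_stratum = {status: _pct(sub) for status, sub in kept.groupby("cci_status") if len(sub)}

    per_field = (
        kept.groupby(["region_id", "field_id", "cci_status"])
        .agg(n_cells=("nucleus_id", "size"), pct_any_foci=("any_foci", "mean"), pct_high_foci=("high_foci", "mean"))
        .reset_index()
    )
    per_field["pct_any_foci"] *= 100.0
    per_field["pct_high_foci"] *= 100.0
    per_region = (
        kept.groupby(["region_id", "cci_status"])
        .agg(n_cells=("nucleus_id", "size"), pct_any_foci=("any_foci", "mean"), pct_high_foci=("high_foci", "mean"))
        .reset_index()
    )
    per_region["pct_any_foci"] *= 100.0
    per_region["pct_high_foci"] *= 100.0

    per_field_means = {
        status: {
            "pct_any_foci": float(sub["pct_any_foci"].mean()),
            "pct_high_foci": float(sub["pct_high_foci"].mean()),
        }
        for status, sub in per_field.groupby("cci_status")
    }
    return FociReport(
        per_stratum=per_stratum,
        per_field=per_field,
        per_region=per_region,
        per_field_means=per_field_means,
        qc_flags=qc,
    )
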