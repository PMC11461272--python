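"""Spheroid diameter and hypoxia-reporter fluorescence over a dose x time grid.

Each well image holds one spheroid.  The spheroid is segmented from the
brightfield channel (dark object on a bright background: Otsu on the inverted
image, hole filling, largest component), its size is summarised as the
equivalent-circle diameter, and the red hypoxia-reporter intensity is the
masked mean over the spheroid.  Intensities are summarised per (dose, time)
condition relative to the same-timepoint untreated (dose 0) control, whose
ratio is 1 by construction.  Disaggregated spheroids at cytotoxic doses are
flagged by a circularity check rather than excluded silently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats, ndimage
from skimage.filters import threshold_otsu
from skimage.measure import perimeter as _perimeter

from .io import SectionImage
from .phantoms import SpheroidWell


@dataclass
class SpheroidObservation:
    """One quantified well."""

    well_id: str
    dose_mM: float
    timepoint_h: float
    diameter_um: float
    mean_red_intensity: float
    qc_pass: bool
    qc_notes: str = ""
    experiment_id: str = "exp1"


def detect_spheroid(
    brightfield: np.ndarray,
    um_per_px: float = 1.0,
    min_area_px: int = 100,
    circularity_min: float = 0.6,
) -> tuple[np.ndarray, float, bool, str]:
    """Segment the spheroid from a brightfield well image.

    Returns ``(mask, diameter_um, qc_pass, qc_notes)``.  The mask is the
    largest dark connected component after Otsu thresholding of the inverted
    image, hole-filled; the diameter is the equivalent-circle diameter from
    the mask area.  QC fails when no component reaches ``min_area_px``; extra
    large components (possible debris or a second spheroid) and low
    circularity (possible disaggregation) are recorded as warnings.
    """
    notes: list[str] = []
    if brightfield.min() == brightfield.max():
        return np.zeros(brightfield.shape, dtype=bool), 0.0, False, "blank well"
    inv = brightfield.max() - brightfield
    t = threshold_otsu(inv)
    binary = ndimage.binary_fill_holes(inv > t)
    labels, n = ndimage.label(binary)
    if n == 0:
        return np.zeros(brightfield.shape, dtype=bool), 0.0, False, "no object found"
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    order = np.argsort(sizes)[::-1]
    if sizes[order[0]] < min_area_px:
        return np.zeros(brightfield.shape, dtype=bool), 0.0, False, (
            f"largest object {int(sizes[order[0]])} px below minimum {min_area_px}"
        )
    if n > 1 and sizes[order[1]] >= min_area_px:
        notes.append(f"{n} objects above minimum area; largest selected")
    mask = labels == (order[0] + 1)
    area = float(mask.sum())
    diameter_um = 2.0 * np.sqrt(area / np.pi) * um_per_px
    per = _perimeter(mask)
    if per > 0:
        circularity = 4.0 * np.pi * area / per**2
        if circularity < circularity_min:
            notes.append(f"low circularity {circularity:.2f} (possible disaggregation)")
    return mask, float(diameter_um), True, "; ".join(notes)


def mean_red_intensity(red_channel: np.ndarray, spheroid_mask: np.ndarray) -> float:
    """Arithmetic mean of the red channel over the spheroid mask."""
    m = spheroid_mask.astype(bool)
    if not m.any():
        raise ValueError("empty spheroid mask")
    if m.shape != red_channel.shape:
        raise ValueError(f"shape mismatch: red {red_channel.shape}, mask {m.shape}")
    return float(red_channel[m].mean())


def measure_well(well: SpheroidWell, **detect_kwargs) -> SpheroidObservation:
    """Quantify one simulated (or loaded) well image."""
    return measure_image(
        well.image,
        well_id=well.well_id,
        dose_mM=well.dose_mM,
        timepoint_h=well.timepoint_h,
        experiment_id=well.experiment_id,
        **detect_kwargs,
    )


def measure_image(
    image: SectionImage,
    well_id: str,
    dose_mM: float,
    timepoint_h: float,
    experiment_id: str = "exp1",
    **detect_kwargs,
) -> SpheroidObservation:
    mask, diameter, ok, notes = detect_spheroid(
        image.channels["brightfield"], um_per_px=image.um_per_px, **detect_kwargs
    )
    intensity = mean_red_intensity(image.channels["red_hypoxia"], mask) if ok else float("nan")
    return SpheroidObservation(
        well_id=well_id,
        dose_mM=dose_mM,
        timepoint_h=timepoint_h,
        diameter_um=diameter,
        mean_red_intensity=intensity,
        qc_pass=ok,
        qc_notes=notes,
        experiment_id=experiment_id,
    )


def observations_to_frame(observations) -> pd.DataFrame:
    if isinstance(observations, pd.DataFrame):
        return observations
    return pd.DataFrame([o.__dict__ for o in observations])


def dose_time_summary(observations, pairing: str | None = None) -> pd.DataFrame:
    """Summarise intensity per (dose, time) relative to the untreated control.

    For every condition cell: n, the ratio of the mean intensity to the
    same-timepoint dose-0 control mean (exactly 1 for the control itself), the
    SD of the per-well ratios, and a two-sided t-test against the control —
    paired across replicate experiments when ``pairing`` names the replicate
    column (e.g. ``"experiment_id"``) and more than one replicate exists, else
    the unpaired Welch variant.
    """
    df = observations_to_frame(observations)
    df = df[df["qc_pass"]].copy()
    rows = []
    for t, sub_t in df.groupby("timepoint_h"):
        ctrl = sub_t[sub_t["dose_mM"] == 0]
        if ctrl.empty:
            raise ValueError(f"missing dose-0 control at timepoint {t} h")
        ctrl_mean = float(ctrl["mean_red_intensity"].mean())
        for dose, cell in sub_t.groupby("dose_mM"):
            vals = cell["mean_red_intensity"].to_numpy(dtype=float)
            if len(vals) < 2:
                raise ValueError(f"condition (dose={dose}, t={t}) has n={len(vals)} < 2")
            ratio = float(vals.mean()) / ctrl_mean
            ratio_sd = float(np.std(vals / ctrl_mean, ddof=1))
            if dose == 0:
                p = 1.0
                tstat = 0.0
            elif pairing is not None and df[pairing].nunique() > 1:
                a = cell.groupby(pairing)["mean_red_intensity"].mean()
                b = ctrl.groupby(pairing)["mean_red_intensity"].mean()
                common = a.index.intersection(b.index)
                if len(common) < 2:
                    res = stats.ttest_ind(vals, ctrl["mean_red_intensity"], equal_var=False)
                    tstat, p = float(res.statistic), float(res.pvalue)
                else:
                    diffs = a.loc[common].to_numpy(float) - b.loc[common].to_numpy(float)
                    if np.allclose(diffs, 0):
                        tstat, p = 0.0, 1.0
                    else:
                        res = stats.ttest_rel(a.loc[common], b.loc[common])
                        tstat, p = float(res.statistic), float(res.pvalue)
            else:
                if np.array_equal(np.sort(vals), np.sort(ctrl["mean_red_intensity"].to_numpy(float))):
                    tstat, p = 0.0, 1.0
                else:
                    res = stats.ttest_ind(vals, ctrl["mean_red_intensity"], equal_var=False)
                    tstat, p = float(res.statistic), float(res.pvalue)
            rows.append(
                {
                    "dose_mM": dose,
                    "timepoint_h": t,
                    "n": int(len(vals)),
                    "mean_intensity": float(vals.mean()),
                    "ratio_to_control": ratio,
                    "ratio_sd": ratio_sd,
                    "t": tstat,
                    "p_vs_control": p,
                    "significant_5pct": bool(p < 0.05),
                }
            )
    return pd.DataFrame(rows).sort_values(["timepoint_h", "dose_mM"]).reset_index(drop=True)
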