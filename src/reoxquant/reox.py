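"""Reoxygenation scoring: log2 fold-change statistics, calls and group summaries.

Two distinct log2 fold-change (log2Fc) statistics are computed per tumour:

* the *area* log2Fc — ``log2(pct_cci / pct_pimo)`` on the percent areas of the
  two marker masks, describing the overall shift between baseline and
  post-treatment hypoxia staining;
* the *integrated-density reoxygenation* log2Fc — the ratio of integrated
  density over the full baseline (CCI-103F) mask to that over the overlap
  region still hypoxic after treatment.  With uniform staining intensity this
  equals ``-log2(1 - f)`` for a reoxygenated fraction *f* of the baseline
  mask.

Both ratios are epsilon-regularised against empty masks; activation of the
regulariser is flagged rather than silent.  The per-tumour call applies the
fixed thresholds: log2Fc < 0 means reoxygenation absent, log2Fc > 1 means
reoxygenated, and the closed interval [0, 1] (including both boundaries) is
indeterminate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import SectionImage, to_8bit
from .masks import (
    Category,
    CategoryMap,
    MarkerMask,
    classify_categories,
    integrated_density,
    otsu_threshold,
    percent_area,
    preset_threshold,
)

ReoxCall = Literal["absent", "indeterminate", "reoxygenated"]

#: call thresholds: strictly below CALL_ABSENT_BELOW -> absent,
#: strictly above CALL_REOX_ABOVE -> reoxygenated, else indeterminate.
CALL_ABSENT_BELOW = 0.0
CALL_REOX_ABOVE = 1.0


class Log2FC(NamedTuple):
    """A log2 fold change plus a flag recording epsilon activation."""

    value: float
    epsilon_activated: bool

    def __float__(self) -> float:  # lets callers treat the result as a number
        return self.value


@dataclass
class ReoxygenationReport:
    """Per-tumour reoxygenation quantification."""

    tumour_id: str
    group: str  # non_injected | vehicle | kortuc
    pct_cci: float
    pct_pimo: float
    area_log2fc: float
    id_cci_total: float
    id_overlap: float
    id_cci_only: float
    reox_log2fc: float
    call: ReoxCall
    epsilon_used: bool

    def as_row(self) -> dict:
        return dict(self.__dict__)


def area_log2fc(pct_cci: float, pct_pimo: float, epsilon: float = 0.01) -> Log2FC:
    """log2 fold change of the two markers' percent areas.

    ``log2((pct_cci + eps) / (pct_pimo + eps))`` with ``eps`` in percentage
    points (default 0.01), applied only when either input is zero; the flag
    records whether it was needed.
    """
    if pct_cci < 0 or pct_pimo < 0:
        raise ValueError(f"percent areas must be nonnegative, got {pct_cci}, {pct_pimo}")
    eps_needed = pct_cci == 0 or pct_pimo == 0
    eps = epsilon if eps_needed else 0.0
    return Log2FC(math.log2((pct_cci + eps) / (pct_pimo + eps)), eps_needed)


def reox_log2fc(
    cci_channel: np.ndarray,
    cci_mask: np.ndarray | MarkerMask,
    overlap_mask: np.ndarray | MarkerMask,
    epsilon: float = 1.0,
    numerator: Literal["cci_total", "cci_only"] = "cci_total",
) -> Log2FC:
    """Integrated-density reoxygenation log2 fold change.

    The numerator is the integrated density of the CCI-103F channel over the
    full baseline mask (or, with ``numerator="cci_only"``, over the
    baseline-only region ``CCI \\ overlap``); the denominator is the
    integrated density over the overlap region still pimonidazole-positive.
    ``epsilon`` (intensity units, default 1) regularises empty masks; the
    flag records its activation.
    """
    cm = cci_mask.mask if isinstance(cci_mask, MarkerMask) else cci_mask.astype(bool)
    om = overlap_mask.mask if isinstance(overlap_mask, MarkerMask) else overlap_mask.astype(bool)
    if np.any(om & ~cm):
        raise ValueError("overlap mask is not a subset of the CCI mask")
    if numerator == "cci_only":
        num = integrated_density(cci_channel, cm & ~om)
    else:
        num = integrated_density(cci_channel, cm)
    den = integrated_density(cci_channel, om)
    eps_needed = num == 0 or den == 0
    eps = epsilon if eps_needed else 0.0
    return Log2FC(math.log2((num + eps) / (den + eps)), eps_needed)


def call_reoxygenation(value: float) -> ReoxCall:
    """Classify a reoxygenation log2Fc with the fixed strict thresholds."""
    v = float(value)
    if not math.isfinite(v):
        raise ValueError(f"log2Fc must be finite, got {value}")
    if v < CALL_ABSENT_BELOW:
        return "absent"
    if v > CALL_REOX_ABOVE:
        return "reoxygenated"
    return "indeterminate"


def score_section(
    image: SectionImage,
    roi: np.ndarray,
    tumour_id: str = "tumour",
    group: str = "kortuc",
    threshold_method: Literal["otsu", "preset"] = "otsu",
    preset_value: float | None = None,
    area_epsilon: float = 0.01,
    id_epsilon: float = 1.0,
    numerator: Literal["cci_total", "cci_only"] = "cci_total",
) -> tuple[ReoxygenationReport, CategoryMap]:
    """Run the full per-tumour quantification on one dual-marker section.

    Channels are converted to 8 bit, thresholded inside the ROI (Otsu by
    default, or a global preset), combined into the category map, and both
    log2Fc statistics and the reoxygenation call are computed.
    """
    cci8 = to_8bit(image.channels["cci103f"], image.bit_depth)
    pimo8 = to_8bit(image.channels["pimonidazole"], image.bit_depth)
    if threshold_method == "preset":
        if preset_value is None:
            raise ValueError("preset thresholding requires preset_value")
        cci_m = preset_threshold(cci8, roi, preset_value, marker="cci103f")
        pimo_m = preset_threshold(pimo8, roi, preset_value, marker="pimonidazole")
    else:
        cci_m = otsu_threshold(cci8, roi, marker="cci103f")
        pimo_m = otsu_threshold(pimo8, roi, marker="pimonidazole")
    cmap = classify_categories(cci_m, pimo_m, roi)
    overlap = cmap.mask(Category.NO_CHANGE)

    pct_cci = percent_area(cci_m, roi)
    pct_pimo = percent_area(pimo_m, roi)
    a_fc = area_log2fc(pct_cci, pct_pimo, epsilon=area_epsilon)
    r_fc = reox_log2fc(cci8, cci_m, overlap, epsilon=id_epsilon, numerator=numerator)
    report = ReoxygenationReport(
        tumour_id=tumour_id,
        group=group,
        pct_cci=pct_cci,
        pct_pimo=pct_pimo,
        area_log2fc=a_fc.value,
        id_cci_total=integrated_density(cci8, cci_m.mask),
        id_overlap=integrated_density(cci8, overlap),
        id_cci_only=integrated_density(cci8, cci_m.mask & ~overlap),
        reox_log2fc=r_fc.value,
        call=call_reoxygenation(r_fc.value),
        epsilon_used=a_fc.epsilon_activated or r_fc.epsilon_activated,
    )
    return report, cmap


def reports_to_frame(reports: Sequence[ReoxygenationReport]) -> pd.DataFrame:
    return pd.DataFrame([r.as_row() for r in reports])


def group_summary(
    reports: Sequence[ReoxygenationReport] | pd.DataFrame,
    value: str = "reox_log2fc",
    group: str = "group",
    compare: Sequence[tuple[str, str]] | None = None,
    pairing_key: str | None = None,
) -> dict:
    """Per-group mean +/- SD plus two-sided t-tests between groups.

    Unpaired comparisons use the Welch variant (unequal variances); an exact
    paired test is used only when ``pairing_key`` names a column aligning
    observations across the two groups.  Significance is read at the 5% level.
    """
    df = reports_to_frame(reports) if not isinstance(reports, pd.DataFrame) else reports
    groups = {g: sub[value].to_numpy(dtype=float) for g, sub in df.groupby(group)}
    too_small = [g for g, v in groups.items() if len(v) < 2]
    if too_small:
        raise ValueError(f"groups with fewer than 2 observations: {too_small}")
    summary: dict = {
        "per_group": {
            g: {"n": int(len(v)), "mean": float(np.mean(v)), "sd": float(np.std(v, ddof=1))}
            for g, v in groups.items()
        },
        "tests": [],
    }
    if compare is None:
        names = sorted(groups)
        compare = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    for a, b in compare:
        if a not in groups or b not in groups:
            raise ValueError(f"unknown group in comparison ({a}, {b})")
        va, vb = groups[a], groups[b]
        if pairing_key is not None:
            da = df[df[group] == a].set_index(pairing_key)[value]
            db = df[df[group] == b].set_index(pairing_key)[value]
            common = da.index.intersection(db.index)
            if len(common) < 2:
                raise ValueError(f"fewer than 2 paired observations for ({a}, {b})")
            diffs = da.loc[common].to_numpy(float) - db.loc[common].to_numpy(float)
            if np.allclose(diffs, 0):
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_rel(da.loc[common], db.loc[common])
            kind = "paired"
        else:
            res = stats.ttest_ind(va, vb, equal_var=False)
            t, p = float(res.statistic), float(res.pvalue)
            kind = "welch"
        summary["tests"].append(
            {
                "groups": [a, b],
                "kind": kind,
                "t": float(t),
                "p": float(p),
                "significant_5pct": bool(p < 0.05),
            }
        )
    return summary
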