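"""Synthetic fluorescence-microscopy phantoms with known ground truth.

Three generators emulate the study designs the analysis modules consume:

* :func:`generate_section_phantom` — paired baseline/post-treatment hypoxia
  marker images (CCI-103F / pimonidazole) over a tumour ROI, with a
  controllable reoxygenated fraction, new-hypoxia fraction and overlap.
  Hypoxic geometry is the level set of a smoothed random field, giving the
  patchy, multi-blob appearance of perfusion-limited hypoxia rather than a
  single disc.
* :func:`generate_foci_phantom` — Hoechst-like nuclei with punctate
  phospho-ATM foci drawn from a per-stratum count distribution, plus a
  per-nucleus baseline-hypoxia (CCI-103F) status channel.
* :func:`generate_spheroid_series` — a dose x time grid of well images:
  a brightfield disc and a red hypoxia-reporter channel whose core intensity
  is scaled by a dose- and time-dependent clearance multiplier that recovers
  toward 1 at late timepoints (hypoxia re-emergence).

All generators are bit-deterministic under their seed, emit 16-bit images
(8-bit conversion is the analysis modules' job), and record ground truth
(masks, category fractions, per-nucleus counts, clearance multipliers) that
is exactly recomputable from the emitted rasters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator
from scipy import ndimage

import tifffile

from .io import RoiPolygon, SectionImage, rasterize_roi, write_section

U16_MAX = 65535


# ---------------------------------------------------------------------------
# parameter models
# ---------------------------------------------------------------------------


class SectionPhantomParams(BaseModel):
    """Parameters of a dual-marker tumour-section phantom."""

    image_height_px: int = Field(256, gt=0)
    image_width_px: int = Field(256, gt=0)
    roi_polygon: list[tuple[float, float]] = Field(default=None, validate_default=True)
    baseline_hypoxic_fraction: float = Field(0.3, ge=0.0, le=1.0)
    reoxygenated_fraction: float = Field(0.5, ge=0.0, le=1.0)
    new_hypoxia_fraction: float = Field(0.0, ge=0.0, le=1.0)
    foreground_intensity_mean: float = Field(40000.0, gt=0.0)
    background_intensity_mean: float = Field(5000.0, ge=0.0)
    noise_sd: float = Field(0.0, ge=0.0)
    blob_scale_px: float = Field(16.0, gt=0.0)
    um_per_px: float = Field(1.0, gt=0.0)
    seed: int = 0

    @field_validator("roi_polygon", mode="before")
    @classmethod
    def _default_roi(cls, v, info):
        if v is None:
            h = info.data.get("image_height_px", 256)
            w = info.data.get("image_width_px", 256)
            m_y, m_x = max(1, h // 16), max(1, w // 16)
            v = [(m_x, m_y), (w - m_x, m_y), (w - m_x, h - m_y), (m_x, h - m_y)]
        if len(v) < 3:
            raise ValueError("roi_polygon needs at least 3 vertices")
        return [(float(x), float(y)) for x, y in v]

    @model_validator(mode="after")
    def _check(self):
        if self.baseline_hypoxic_fraction + self.new_hypoxia_fraction > 1.0:
            raise ValueError(
                "infeasible fractions: baseline_hypoxic_fraction + "
                "new_hypoxia_fraction = "
                f"{self.baseline_hypoxic_fraction + self.new_hypoxia_fraction:.3f} > 1"
            )
        if self.foreground_intensity_mean <= self.background_intensity_mean:
            raise ValueError(
                "foreground_intensity_mean must exceed background_intensity_mean"
            )
        xs = [x for x, _ in self.roi_polygon]
        ys = [y for _, y in self.roi_polygon]
        if min(xs) < 0 or min(ys) < 0 or max(xs) > self.image_width_px or max(ys) > self.image_height_px:
            raise ValueError("roi_polygon lies outside the image bounds")
        return self


class FociCountDistribution(BaseModel):
    """Per-stratum distribution of foci counts per nucleus."""

    name: Literal["poisson", "fixed"] = "poisson"
    mean: float = Field(4.0, ge=0.0)
    mean_cci_positive: float | None = Field(None, ge=0.0)
    mean_cci_negative: float | None = Field(None, ge=0.0)

    def stratum_mean(self, cci_positive: bool) -> float:
        if cci_positive and self.mean_cci_positive is not None:
            return self.mean_cci_positive
        if not cci_positive and self.mean_cci_negative is not None:
            return self.mean_cci_negative
        return self.mean

    def sample(self, rng: np.random.Generator, cci_positive: bool) -> int:
        mu = self.stratum_mean(cci_positive)
        if self.name == "fixed":
            return int(round(mu))
        return int(rng.poisson(mu))


class FociPhantomParams(BaseModel):
    """Parameters of a nuclei-plus-foci phantom."""

    image_height_px: int = Field(512, gt=0)
    image_width_px: int = Field(512, gt=0)
    n_nuclei: int = Field(100, gt=0)
    nucleus_radius_px: float = Field(10.0, gt=0.0)
    foci_count_distribution: FociCountDistribution = Field(default_factory=FociCountDistribution)
    foci_radius_px: float = Field(1.6, gt=0.0)
    foci_intensity: float = Field(24000.0, gt=0.0)
    fraction_cci_positive: float = Field(0.5, ge=0.0, le=1.0)
    nucleus_intensity: float = Field(30000.0, gt=0.0)
    background_intensity: float = Field(2000.0, ge=0.0)
    noise_sd: float = Field(0.0, ge=0.0)
    seed: int = 0


class CoreClearanceModel(BaseModel):
    """Dose- and time-dependent hypoxic-core fluorescence multiplier.

    ``multiplier(dose, t) = 1 - s(dose) * exp(-max(t - onset, 0) / tau(dose))``
    with Hill-type suppression ``s(d) = d^h / (d^h + k50^h)`` and a recovery
    timescale ``tau(d) = tau0 * (1 + d / k50)`` that lengthens with dose: high
    doses clear the core almost completely and stay cleared for hours, while
    low doses recover toward baseline (hypoxia re-emerges) by 24 h.  At dose 0
    the multiplier is exactly 1 at every timepoint.
    """

    k50_mM: float = Field(1.2, gt=0.0)
    hill: float = Field(2.0, gt=0.0)
    onset_h: float = Field(1.0, ge=0.0)
    tau0_h: float = Field(8.0, gt=0.0)

    def multiplier(self, dose_mM: float, timepoint_h: float) -> float:
        if dose_mM < 0:
            raise ValueError("dose must be nonnegative")
        if dose_mM == 0:
            return 1.0
        s = dose_mM**self.hill / (dose_mM**self.hill + self.k50_mM**self.hill)
        tau = self.tau0_h * (1.0 + dose_mM / self.k50_mM)
        decay = np.exp(-max(timepoint_h - self.onset_h, 0.0) / tau)
        return float(1.0 - s * decay)


class SpheroidPhantomParams(BaseModel):
    """Parameters of a spheroid dose x time well-image series."""

    diameter_range_um: tuple[float, float] = (400.0, 700.0)
    um_per_px: float = Field(4.0, gt=0.0)
    doses_mM: list[float] = Field(default_factory=lambda: [0.0, 0.6, 1.2, 2.4, 4.8, 9.6])
    timepoints_h: list[float] = Field(default_factory=lambda: [1.0, 6.0, 24.0])
    n_per_condition: int = Field(14, gt=0)
    core_clearance_model: CoreClearanceModel = Field(default_factory=CoreClearanceModel)
    core_radius_fraction: float = Field(0.6, gt=0.0, le=1.0)
    core_intensity: float = Field(30000.0, gt=0.0)
    brightfield_background: float = Field(50000.0, gt=0.0)
    brightfield_spheroid: float = Field(12000.0, ge=0.0)
    noise_sd: float = Field(0.0, ge=0.0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        lo, hi = self.diameter_range_um
        if not (0 < lo <= hi):
            raise ValueError("diameter_range_um must satisfy 0 < lo <= hi")
        if 0.0 not in self.doses_mM:
            raise ValueError("doses_mM must include the dose-0 control")
        return self


# ---------------------------------------------------------------------------
# ground truth containers
# ---------------------------------------------------------------------------


@dataclass
class SectionGroundTruth:
    """Generator ground truth: true masks, fractions and per-nucleus counts.

    Section phantoms populate the mask and fraction fields; foci phantoms the
    per-nucleus fields; spheroid series the per-well table.  Fractions are
    recomputed from the emitted masks at construction time, so they are exact
    by definition.
    """

    seed: int
    true_cci_mask: np.ndarray | None = None
    true_pimo_mask: np.ndarray | None = None
    roi_mask: np.ndarray | None = None
    true_category_fractions: dict[str, float] = field(default_factory=dict)
    true_foci_counts: np.ndarray | None = None
    nucleus_labels: np.ndarray | None = None
    nucleus_centroids: np.ndarray | None = None
    cci_status: np.ndarray | None = None
    wells: list[dict] = field(default_factory=list)


@dataclass
class SpheroidWell:
    """One simulated well: a two-channel image plus its condition metadata."""

    well_id: str
    dose_mM: float
    timepoint_h: float
    image: SectionImage
    true_diameter_um: float
    true_multiplier: float
    true_mean_intensity: float
    experiment_id: str = "exp1"


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], scale: float) -> np.ndarray:
    """Low-pass-filtered Gaussian random field; its level sets are blobs."""
    raw = rng.standard_normal(shape)
    return ndimage.gaussian_filter(raw, sigma=scale)


def _top_k_mask(values: np.ndarray, candidates: np.ndarray, k: int) -> np.ndarray:
    """Boolean mask of the k candidate pixels with the largest field values."""
    out = np.zeros(values.shape, dtype=bool)
    if k <= 0:
        return out
    idx = np.flatnonzero(candidates)
    order = np.argsort(values.ravel()[idx], kind="stable")[::-1]
    out.ravel()[idx[order[:k]]] = True
    return out


def _render_channel(
    mask: np.ndarray,
    fg: float,
    bg: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    img = np.where(mask, fg, bg).astype(np.float64)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, U16_MAX).astype(np.uint16)


def _carve_reoxygenated(
    cci: np.ndarray, target: int, rng: np.random.Generator, tiebreak: np.ndarray
) -> np.ndarray:
    """Remove ``target`` pixels from the baseline mask: whole blobs first,
    then boundary erosion of one remaining blob, greedily and deterministically.

    Returns the boolean mask of removed (reoxygenated) pixels, exactly
    ``target`` pixels in size.
    """
    removed = np.zeros_like(cci)
    if target <= 0:
        return removed
    labels, n = ndimage.label(cci)
    sizes = ndimage.sum_labels(np.ones_like(cci, dtype=np.int64), labels, index=np.arange(1, n + 1))
    order = rng.permutation(n) + 1  # blob visit order, seed-deterministic
    budget = target
    partial_label = None
    for lab in order:
        size = int(sizes[lab - 1])
        if size <= budget:
            removed |= labels == lab
            budget -= size
            if budget == 0:
                return removed
        elif partial_label is None:
            partial_label = int(lab)
    if partial_label is None:  # every blob consumed but budget remains
        return removed
    blob = labels == partial_label
    # peel boundary layers until the remaining budget fits inside one layer
    while budget > 0:
        interior = ndimage.binary_erosion(blob)
        boundary = blob & ~interior
        n_boundary = int(boundary.sum())
        if n_boundary == 0:
            boundary, n_boundary = blob, int(blob.sum())
        if n_boundary <= budget:
            removed |= boundary
            blob = blob & ~boundary
            budget -= n_boundary
        else:
            # final partial layer: break ties by the underlying field value
            idx = np.flatnonzero(boundary)
            sub = np.argsort(tiebreak.ravel()[idx], kind="stable")[:budget]
            removed.ravel()[idx[sub]] = True
            budget = 0
    return removed


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def generate_section_phantom(
    params: SectionPhantomParams,
) -> tuple[SectionImage, SectionGroundTruth]:
    """Generate a paired CCI-103F / pimonidazole section phantom.

    The baseline (CCI-103F) mask is the top ``baseline_hypoxic_fraction`` of
    ROI pixels of a smoothed random field, so it is a union of blobs whose
    area matches the request to within one pixel.  The reoxygenated region is
    carved from it blob-by-blob (plus partial boundary erosion) until exactly
    ``reoxygenated_fraction`` of the baseline mask is removed; new hypoxia is
    an independent blob set of ``new_hypoxia_fraction`` of the ROI drawn from
    the CCI-negative remainder.  The pimonidazole mask is
    ``(CCI minus reoxygenated) union new-hypoxia``.
    """
    rng = np.random.default_rng(params.seed)
    shape = (params.image_height_px, params.image_width_px)
    roi = rasterize_roi(RoiPolygon(params.roi_polygon), shape)
    n_roi = int(roi.sum())
    if n_roi == 0:
        raise ValueError("ROI polygon rasterises to an empty mask")

    base_field = _smooth_field(rng, shape, params.blob_scale_px)
    k_cci = int(round(params.baseline_hypoxic_fraction * n_roi))
    cci = _top_k_mask(base_field, roi, k_cci)

    target_reox = int(round(params.reoxygenated_fraction * k_cci))
    reox = _carve_reoxygenated(cci, target_reox, rng, tiebreak=base_field)

    new_field = _smooth_field(rng, shape, params.blob_scale_px)
    k_new = int(round(params.new_hypoxia_fraction * n_roi))
    new_hyp = _top_k_mask(new_field, roi & ~cci, k_new)

    pimo = (cci & ~reox) | new_hyp

    image = SectionImage(
        channels={
            "cci103f": _render_channel(
                cci,
                params.foreground_intensity_mean,
                params.background_intensity_mean,
                params.noise_sd,
                rng,
            ),
            "pimonidazole": _render_channel(
                pimo,
                params.foreground_intensity_mean,
                params.background_intensity_mean,
                params.noise_sd,
                rng,
            ),
        },
        um_per_px=params.um_per_px,
        bit_depth=16,
        provenance=f"section phantom seed={params.seed}",
    )
    fractions = {
        "reoxygenated": float((cci & ~pimo).sum() / n_roi),
        "new_hypoxia": float((pimo & ~cci).sum() / n_roi),
        "no_change": float((cci & pimo).sum() / n_roi),
    }
    truth = SectionGroundTruth(
        seed=params.seed,
        true_cci_mask=cci,
        true_pimo_mask=pimo,
        roi_mask=roi,
        true_category_fractions=fractions,
    )
    return image, truth


def _place_foci(
    rng: np.random.Generator,
    count: int,
    centre: tuple[float, float],
    placement_radius: float,
    min_separation: float,
    max_attempts: int = 400,
) -> np.ndarray:
    """Sample up to ``count`` focus centres inside a disc, pairwise separated.

    Placement is rejection sampling at ``min_separation``; if the disc
    saturates, the separation is relaxed stepwise (never below 2 px) and, at
    worst, fewer centres are returned.  Callers record the number actually
    placed as the ground truth, so truth and rendering always agree.
    """
    for sep in (min_separation, 0.8 * min_separation, 0.64 * min_separation):
        sep = max(sep, 2.0)
        pts: list[tuple[float, float]] = []
        attempts = 0
        while len(pts) < count and attempts < max_attempts * max(count, 1):
            attempts += 1
            r = placement_radius * np.sqrt(rng.uniform())
            theta = rng.uniform(0, 2 * np.pi)
            y = centre[0] + r * np.sin(theta)
            x = centre[1] + r * np.cos(theta)
            if all((y - py) ** 2 + (x - px) ** 2 >= sep**2 for py, px in pts):
                pts.append((y, x))
        if len(pts) == count:
            break
    return np.asarray(pts, dtype=np.float64).reshape(-1, 2)


def generate_foci_phantom(
    params: FociPhantomParams,
) -> tuple[SectionImage, SectionGroundTruth]:
    """Generate nuclei with punctate phospho-ATM foci and CCI-103F status.

    Nuclei are discs placed on a jittered grid, non-overlapping by
    construction.  Foci are rendered as 2-D Gaussian spots (sigma =
    ``foci_radius_px / 2``) whose centres lie inside the parent nucleus with a
    minimum centre-to-centre separation of 2.5x the focus radius, keeping
    counts well defined (no scale-space merging) at zero noise.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.image_height_px, params.image_width_px
    r = params.nucleus_radius_px
    pitch = int(np.ceil(2 * r + 6))
    rows = (h - pitch // 2) // pitch
    cols = (w - pitch // 2) // pitch
    n_sites = rows * cols
    if params.n_nuclei > n_sites:
        raise ValueError(
            f"n_nuclei={params.n_nuclei} infeasible: the {h}x{w} image holds at "
            f"most {n_sites} non-overlapping nuclei of radius {r}"
        )
    sites = rng.permutation(n_sites)[: params.n_nuclei]
    jitter_max = (pitch - 2 * r - 2) / 2.0
    centroids = np.empty((params.n_nuclei, 2))
    for i, s in enumerate(sites):
        gy, gx = divmod(int(s), cols)
        cy = pitch // 2 + gy * pitch + pitch / 2
        cx = pitch // 2 + gx * pitch + pitch / 2
        if jitter_max > 0:
            cy += rng.uniform(-jitter_max, jitter_max)
            cx += rng.uniform(-jitter_max, jitter_max)
        centroids[i] = (cy, cx)

    yy, xx = np.mgrid[0:h, 0:w]
    nuclei_mask = np.zeros((h, w), dtype=bool)
    labels = np.zeros((h, w), dtype=np.int32)
    for i, (cy, cx) in enumerate(centroids, start=1):
        disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        nuclei_mask |= disc
        labels[disc] = i

    cci_status = rng.uniform(size=params.n_nuclei) < params.fraction_cci_positive
    cci_mask = np.isin(labels, np.flatnonzero(cci_status) + 1) & (labels > 0)

    dist = params.foci_count_distribution
    sigma = params.foci_radius_px / 2.0
    placement_radius = max(r - params.foci_radius_px, 1.0)
    patm = np.full((h, w), params.background_intensity, dtype=np.float64)
    counts = np.zeros(params.n_nuclei, dtype=np.int64)
    for i, (cy, cx) in enumerate(centroids):
        k = dist.sample(rng, bool(cci_status[i]))
        if k == 0:
            counts[i] = 0
            continue
        pts = _place_foci(rng, k, (cy, cx), placement_radius, 2.5 * params.foci_radius_px)
        counts[i] = len(pts)  # at saturation, truth follows what was rendered
        ext = int(np.ceil(5 * sigma))
        for fy, fx in pts:
            r0, r1 = max(int(fy) - ext, 0), min(int(fy) + ext + 1, h)
            c0, c1 = max(int(fx) - ext, 0), min(int(fx) + ext + 1, w)
            sy = yy[r0:r1, c0:c1]
            sx = xx[r0:r1, c0:c1]
            patm[r0:r1, c0:c1] += params.foci_intensity * np.exp(
                -((sy - fy) ** 2 + (sx - fx) ** 2) / (2 * sigma**2)
            )

    nuclei_img = _render_channel(
        nuclei_mask, params.nucleus_intensity, params.background_intensity, params.noise_sd, rng
    )
    cci_img = _render_channel(
        cci_mask, params.nucleus_intensity, params.background_intensity, params.noise_sd, rng
    )
    if params.noise_sd > 0:
        patm = patm + rng.normal(0.0, params.noise_sd, size=patm.shape)
    patm_img = np.clip(np.rint(patm), 0, U16_MAX).astype(np.uint16)

    image = SectionImage(
        channels={"nuclei": nuclei_img, "phospho_atm": patm_img, "cci103f": cci_img},
        bit_depth=16,
        provenance=f"foci phantom seed={params.seed}",
    )
    truth = SectionGroundTruth(
        seed=params.seed,
        true_cci_mask=cci_mask,
        true_foci_counts=counts,
        nucleus_labels=labels,
        nucleus_centroids=centroids,
        cci_status=cci_status,
    )
    return image, truth


def generate_spheroid_series(
    params: SpheroidPhantomParams,
) -> tuple[list[SpheroidWell], SectionGroundTruth]:
    """Generate brightfield + red-fluorescence well images over dose x time.

    Each well holds one spheroid: a dark disc on a bright brightfield
    background, and a red channel whose concentric hypoxic core (radius
    ``core_radius_fraction`` of the spheroid radius) fluoresces at
    ``core_intensity`` scaled by the clearance multiplier for that
    (dose, time) condition; the rest of the red channel is dark.
    """
    rng = np.random.default_rng(params.seed)
    lo, hi = params.diameter_range_um
    max_r_px = hi / 2.0 / params.um_per_px
    size = int(np.ceil(2 * max_r_px + 16))
    yy, xx = np.mgrid[0:size, 0:size]
    cy = cx = size / 2.0
    model = params.core_clearance_model

    wells: list[SpheroidWell] = []
    truth_rows: list[dict] = []
    for t in params.timepoints_h:
        for dose in params.doses_mM:
            m = model.multiplier(dose, t)
            for rep in range(params.n_per_condition):
                diameter = float(rng.uniform(lo, hi))
                r_px = diameter / 2.0 / params.um_per_px
                disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_px**2
                core = (yy - cy) ** 2 + (xx - cx) ** 2 <= (params.core_radius_fraction * r_px) ** 2
                bf = _render_channel(
                    disc, params.brightfield_spheroid, params.brightfield_background,
                    params.noise_sd, rng,
                )
                red = _render_channel(
                    core, params.core_intensity * m, 0.0, params.noise_sd, rng
                )
                mean_true = float(params.core_intensity * m * core.sum() / disc.sum())
                well_id = f"d{dose:g}_t{t:g}_r{rep}"
                image = SectionImage(
                    channels={"brightfield": bf, "red_hypoxia": red},
                    um_per_px=params.um_per_px,
                    bit_depth=16,
                    provenance=f"spheroid phantom {well_id} seed={params.seed}",
                )
                wells.append(
                    SpheroidWell(
                        well_id=well_id,
                        dose_mM=dose,
                        timepoint_h=t,
                        image=image,
                        true_diameter_um=diameter,
                        true_multiplier=m,
                        true_mean_intensity=mean_true,
                    )
                )
                truth_rows.append(
                    {
                        "well_id": well_id,
                        "dose_mM": dose,
                        "timepoint_h": t,
                        "true_diameter_um": diameter,
                        "true_multiplier": m,
                        "true_mean_intensity": mean_true,
                    }
                )
    truth = SectionGroundTruth(seed=params.seed, wells=truth_rows)
    return wells, truth


# ---------------------------------------------------------------------------
# on-disk persistence
# ---------------------------------------------------------------------------


def save_phantom(
    image: SectionImage,
    truth: SectionGroundTruth,
    out_dir: str | Path,
    stem: str = "phantom",
) -> Path:
    """Write a phantom as multi-page TIFF + mask TIFFs + a JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_section(image, out / f"{stem}.tif")
    sidecar: dict = {"seed": truth.seed, "true_category_fractions": truth.true_category_fractions}
    for name in ("true_cci_mask", "true_pimo_mask", "roi_mask", "nucleus_labels"):
        arr = getattr(truth, name)
        if arr is not None:
            tifffile.imwrite(out / f"{stem}_{name}.tif", arr.astype(np.uint16))
    if truth.true_foci_counts is not None:
        sidecar["true_foci_counts"] = truth.true_foci_counts.tolist()
    if truth.cci_status is not None:
        sidecar["cci_status"] = truth.cci_status.astype(int).tolist()
    if truth.wells:
        sidecar["wells"] = truth.wells
    (out / f"{stem}_truth.json").write_text(json.dumps(sidecar, indent=2))
    return out / f"{stem}.tif"
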