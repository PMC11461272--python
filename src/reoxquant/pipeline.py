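"""Reproducible orchestration: simulate -> quantify -> foci -> spheroid -> report.

A run is described by one :class:`RunConfig` (a single JSON document with
per-stage blocks).  Every stochastic stage carries an explicit seed; all
randomness is routed through one seeded generator per stage, so identical
config + seeds reproduce byte-identical numeric outputs.  Each run writes a
manifest (config hash, seeds, package version, per-stage output paths) that
suffices to reproduce it; a failing stage halts the run with the stage named
and leaves partial outputs beside a FAILED marker.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import numpy as np
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .foci import aggregate_foci, cells_to_frame, count_foci, score_cells, segment_nuclei
from .phantoms import (
    FociPhantomParams,
    SectionPhantomParams,
    SpheroidPhantomParams,
    generate_foci_phantom,
    generate_section_phantom,
    generate_spheroid_series,
)
from .reox import group_summary, reports_to_frame, score_section
from .spheroid import dose_time_summary, measure_well, observations_to_frame

STAGES = ("sections", "foci", "spheroids")


class SectionStageConfig(BaseModel):
    """Simulate dual-marker sections per treatment group and quantify them."""

    groups: dict[str, int] = Field(
        default_factory=lambda: {"non_injected": 3, "vehicle": 3, "kortuc": 3}
    )
    #: per-group reoxygenated fraction of the baseline hypoxic mask
    reox_fraction_by_group: dict[str, float] = Field(
        default_factory=lambda: {"non_injected": 0.02, "vehicle": 0.05, "kortuc": 0.6}
    )
    #: default phantom carries intensity noise so replicate tumours differ
    phantom: SectionPhantomParams = Field(
        default_factory=lambda: SectionPhantomParams(noise_sd=2000.0)
    )
    threshold_method: Literal["otsu", "preset"] = "otsu"
    preset_value: float | None = None
    area_epsilon: float = 0.01
    id_epsilon: float = 1.0
    numerator: Literal["cci_total", "cci_only"] = "cci_total"
    seed: int | None = None

    @model_validator(mode="after")
    def _check(self):
        missing = set(self.groups) - set(self.reox_fraction_by_group)
        if missing:
            raise ValueError(f"groups without a reox fraction: {sorted(missing)}")
        return self


class FociStageConfig(BaseModel):
    """Simulate a foci phantom and score cells stratified by CCI status."""

    phantom: FociPhantomParams = Field(default_factory=FociPhantomParams)
    min_cells_per_field: int = 50
    min_fields_per_region: int = 5
    min_radius_px: float = 1.0
    max_radius_px: float = 3.5
    min_prominence: float = 0.08
    seed: int | None = None


class SpheroidStageConfig(BaseModel):
    """Simulate and quantify a spheroid dose x time series."""

    phantom: SpheroidPhantomParams = Field(default_factory=SpheroidPhantomParams)
    pairing: str | None = None
    seed: int | None = None


class RunConfig(BaseModel):
    """Full pipeline configuration; every stochastic stage needs a seed."""

    stages: list[Literal["sections", "foci", "spheroids"]] = Field(
        default_factory=lambda: list(STAGES)
    )
    sections: SectionStageConfig = Field(default_factory=SectionStageConfig)
    foci: FociStageConfig = Field(default_factory=FociStageConfig)
    spheroids: SpheroidStageConfig = Field(default_factory=SpheroidStageConfig)
    out_dir: str = "runs/run"

    @model_validator(mode="after")
    def _seeds_explicit(self):
        for name in self.stages:
            if getattr(self, name).seed is None:
                raise ValueError(f"stage {name!r} is stochastic but has no explicit seed")
        return self


def _config_hash(config: RunConfig) -> str:
    canonical = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _write_csv(df, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def _run_sections(cfg: SectionStageConfig, out: Path) -> dict:
    reports = []
    for group, n in sorted(cfg.groups.items()):
        gkey = int.from_bytes(hashlib.sha256(group.encode()).digest()[:4], "big")
        for i in range(n):
            child = np.random.SeedSequence(entropy=cfg.seed, spawn_key=(gkey, i))
            seed = int(child.generate_state(1)[0] % 2**31)
            params = cfg.phantom.model_copy(
                update={"seed": seed, "reoxygenated_fraction": cfg.reox_fraction_by_group[group]}
            )
            image, truth = generate_section_phantom(params)
            report, _ = score_section(
                image,
                truth.roi_mask,
                tumour_id=f"{group}_{i + 1}",
                group=group,
                threshold_method=cfg.threshold_method,
                preset_value=cfg.preset_value,
                area_epsilon=cfg.area_epsilon,
                id_epsilon=cfg.id_epsilon,
                numerator=cfg.numerator,
            )
            reports.append(report)
    df = reports_to_frame(reports)
    _write_csv(df, out / "reoxygenation_reports.csv")
    if all(n >= 2 for n in cfg.groups.values()) and len(cfg.groups) >= 2:
        summary = group_summary(reports)
        (out / "group_summary.json").write_text(json.dumps(summary, indent=2))
    return {"reports_csv": str(out / "reoxygenation_reports.csv"), "n_reports": len(reports)}


def _run_foci(cfg: FociStageConfig, out: Path) -> dict:
    params = cfg.phantom.model_copy(update={"seed": cfg.seed})
    image, truth = generate_foci_phantom(params)
    labels = segment_nuclei(image.channels["nuclei"])
    counts = [
        count_foci(
            image.channels["phospho_atm"],
            labels == lab,
            min_radius_px=cfg.min_radius_px,
            max_radius_px=cfg.max_radius_px,
            min_prominence=cfg.min_prominence,
        )
        for lab in range(1, labels.max() + 1)
    ]
    from .io import to_8bit
    from .masks import otsu_threshold

    cci8 = to_8bit(image.channels["cci103f"], image.bit_depth)
    full = np.ones(cci8.shape, dtype=bool)
    if cci8.min() == cci8.max():  # no CCI-positive nuclei rendered
        cci_mask = np.zeros(cci8.shape, dtype=bool)
    else:
        cci_mask = otsu_threshold(cci8, full, marker="cci103f").mask
    cells = score_cells(labels, counts, cci_mask, region_id=1, field_id=1)
    df = cells_to_frame(cells)
    _write_csv(df, out / "cells.csv")
    report = aggregate_foci(
        cells,
        min_cells_per_field=cfg.min_cells_per_field,
        min_fields_per_region=cfg.min_fields_per_region,
    )
    (out / "foci_summary.json").write_text(
        json.dumps(
            {
                "per_stratum": report.per_stratum,
                "per_field_means": report.per_field_means,
                "qc_flags": report.qc_flags,
            },
            indent=2,
        )
    )
    return {"cells_csv": str(out / "cells.csv"), "n_cells": len(cells)}


def _run_spheroids(cfg: SpheroidStageConfig, out: Path) -> dict:
    params = cfg.phantom.model_copy(update={"seed": cfg.seed})
    wells, _truth = generate_spheroid_series(params)
    obs = [measure_well(w) for w in wells]
    obs_df = observations_to_frame(obs)
    _write_csv(obs_df, out / "spheroid_observations.csv")
    summary = dose_time_summary(obs, pairing=cfg.pairing)
    _write_csv(summary, out / "spheroid_summary.csv")
    return {
        "observations_csv": str(out / "spheroid_observations.csv"),
        "summary_csv": str(out / "spheroid_summary.csv"),
        "n_wells": len(obs),
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order and write a run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": _config_hash(config),
        "config": config.model_dump(mode="json"),
        "version": __version__,
        "stages": {},
    }
    runners = {"sections": _run_sections, "foci": _run_foci, "spheroids": _run_spheroids}
    for name in config.stages:
        try:
            manifest["stages"][name] = runners[name](getattr(config, name), out)
        except Exception as exc:
            (out / "FAILED").write_text(f"stage {name} failed: {exc}\n")
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def run_from_manifest(manifest_path: str | Path, out_dir: str | Path) -> dict:
    """Re-execute a run from its manifest (round-trip reproduction)."""
    manifest = json.loads(Path(manifest_path).read_text())
    cfg = RunConfig.model_validate({**manifest["config"], "out_dir": str(out_dir)})
    return run_pipeline(cfg)
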