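"""End-to-end per-eye quantification and cohort analysis.

``run_quantify`` takes the visit volumes of one eye and executes the
measurement chain per visit — attenuation compensation, BM/CSI
segmentation, thickness map, global Otsu vessel binarization, CVI map —
then registers every visit to the day-of-exudation reference frame,
combines ONH and per-visit exclusion masks there, and reduces the maps
to fovea-centered regional means.  ``run_analyze`` turns a measurement
table into the six longitudinal summary tables with cluster-robust
p-values.
"""

from __future__ import annotations

import json
import time
import tomllib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import maps as cmaps
from . import regions as cregions
from .attenuation import AttenuationParams, compensate_attenuation
from .registration import RigidTransform2D, register_enface, warp
from .stats import format_table, summarize_tables
from .surfaces import ChoroidSegmentationParams, SurfaceSet, apply_corrections, segment_choroid
from .volume import EnFaceMap, OCTVolume, project_slab, quality_gate, write_map

REFERENCE_VISIT = "exudation"


@dataclass
class PipelineConfig:
    """All tunables of the measurement and analysis chain."""

    attenuation: AttenuationParams = field(default_factory=AttenuationParams)
    segmentation: ChoroidSegmentationParams = field(
        default_factory=ChoroidSegmentationParams
    )
    inner_diameter_mm: float = 5.0
    outer_diameter_mm: float = 11.0
    eligibility_threshold: float = 0.10
    min_signal_strength: int = 7
    despeckle_sigma_z: float = 2.0
    rotation_bound_deg: float = 5.0
    rotation_step_deg: float = 0.25
    stats_correction: str = "CR1"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.eligibility_threshold <= 1:
            raise ValueError("eligibility threshold must be in [0, 1]")
        if self.min_signal_strength < 0 or self.min_signal_strength > 10:
            raise ValueError("min_signal_strength must be in 0..10")

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        raw = tomllib.loads(Path(path).read_text())
        att = AttenuationParams(**raw.pop("attenuation", {}))
        seg_raw = raw.pop("segmentation", {})
        seg = ChoroidSegmentationParams(**seg_raw, attenuation=att)
        return cls(attenuation=att, segmentation=seg, **raw)


@dataclass
class EyeQuantification:
    """Per-eye outputs: measurement records plus the per-visit artifacts
    (all maps expressed in the reference-visit frame)."""

    records: pd.DataFrame
    thickness_maps: dict[str, EnFaceMap]
    cvi_maps: dict[str, EnFaceMap]
    surfaces: dict[str, SurfaceSet]
    transforms: dict[str, RigidTransform2D]
    thresholds: dict[str, float]
    eligible: bool
    excluded_fraction: float
    log: list[dict]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(outdir / "measurements.csv", index=False)
        for visit, m in self.thickness_maps.items():
            write_map(m, outdir / f"thickness_{visit}.csv")
        for visit, m in self.cvi_maps.items():
            write_map(m, outdir / f"cvi_{visit}.csv")
        for visit, t in self.transforms.items():
            t.to_json(outdir / f"transform_{visit}.json")
        (outdir / "thresholds.json").write_text(json.dumps(self.thresholds))
        with open(outdir / "log.jsonl", "w") as fh:
            for entry in self.log:
                fh.write(json.dumps(entry) + "\n")


def _log(log: list, stage: str, visit: str, t0: float, **extra) -> None:
    log.append(
        {
            "stage": stage,
            "visit": visit,
            "duration_s": round(time.perf_counter() - t0, 4),
            **extra,
        }
    )


def run_quantify(
    config: PipelineConfig,
    volumes: dict[str, OCTVolume],
    exclusion_masks: Optional[dict[str, np.ndarray]] = None,
    corrections: Optional[dict[str, pd.DataFrame]] = None,
) -> EyeQuantification:
    """Quantify one eye across its visits.

    ``volumes`` maps visit label to the raw volume; the day-of-exudation
    visit is required and serves as the reference frame.  Optional
    ``exclusion_masks`` (per visit, in that visit's frame) are warped to
    the reference frame and their union removed from every visit.
    """
    log: list[dict] = []
    usable: dict[str, OCTVolume] = {}
    for visit, vol in volumes.items():
        t0 = time.perf_counter()
        gate = quality_gate(vol, config.min_signal_strength)
        if not gate:
            _log(log, "quality_gate", visit, t0, skipped=True, reason=gate.reason)
            continue
        _log(log, "quality_gate", visit, t0, skipped=False)
        usable[visit] = vol
    if REFERENCE_VISIT not in usable:
        raise RuntimeError(
            f"reference visit '{REFERENCE_VISIT}' absent or failed the quality gate"
        )

    per_visit: dict[str, dict] = {}
    for visit, vol in usable.items():
        t0 = time.perf_counter()
        comp = compensate_attenuation(vol, config.attenuation)
        surf = segment_choroid(vol, config.segmentation)
        if corrections and visit in corrections:
            surf = apply_corrections(surf, corrections[visit])
        th_map = cmaps.thickness_map(surf, vol.axial_spacing_um)
        slab_vals = cmaps.slab_intensities(comp, surf, config.despeckle_sigma_z)
        threshold = cmaps.otsu_threshold(slab_vals)
        vessels = cmaps.binarize_vessels(comp, surf, threshold, config.despeckle_sigma_z)
        cvi = cmaps.cvi_map(vessels, surf)
        retinal_proj = project_slab(vol, np.zeros(surf.bm.shape), surf.bm, "mean")
        per_visit[visit] = {
            "volume": vol,
            "surfaces": surf,
            "thickness": th_map,
            "cvi": cvi,
            "threshold": threshold,
            "retinal_proj": retinal_proj,
        }
        _log(log, "quantify_visit", visit, t0, otsu_threshold=threshold)

    # registration into the reference frame
    ref = per_visit[REFERENCE_VISIT]
    transforms: dict[str, RigidTransform2D] = {}
    thickness_maps: dict[str, EnFaceMap] = {}
    cvi_maps_out: dict[str, EnFaceMap] = {}
    for visit, data in per_visit.items():
        t0 = time.perf_counter()
        if visit == REFERENCE_VISIT:
            transform = RigidTransform2D(
                reference_visit=REFERENCE_VISIT, moving_visit=visit, score=1.0
            )
        else:
            transform = register_enface(
                data["retinal_proj"],
                ref["retinal_proj"],
                rotation_bound_deg=config.rotation_bound_deg,
                rotation_step_deg=config.rotation_step_deg,
            )
            transform.reference_visit = REFERENCE_VISIT
            transform.moving_visit = visit
        transforms[visit] = transform
        inv = transform.inverse()
        thickness_maps[visit] = warp(data["thickness"], inv)
        cvi_maps_out[visit] = warp(data["cvi"], inv)
        _log(log, "register", visit, t0, score=transform.score)

    # masks in the reference frame
    ref_vol: OCTVolume = ref["volume"]
    shape = ref_vol.intensity.shape[:2]
    maskset = cregions.MaskSet(shape=shape, onh_mask=ref_vol.onh_mask)
    if exclusion_masks:
        for visit, mask in exclusion_masks.items():
            if visit in transforms:
                maskset.visit_exclusions[visit] = warp(
                    mask.astype(bool), transforms[visit].inverse()
                )
    spec = cregions.RegionSpec(
        fovea_center=ref_vol.fovea_center,
        lateral_spacing_um=ref_vol.lateral_spacing_um,
        inner_diameter_mm=config.inner_diameter_mm,
        outer_diameter_mm=config.outer_diameter_mm,
    )
    region_masks = cregions.region_masks(spec, shape)
    eligible, excluded_fraction = cregions.cvi_eligibility(
        maskset.combined_exclusion, region_masks["circle5"], config.eligibility_threshold
    )

    rows = []
    for visit in per_visit:
        vol = per_visit[visit]["volume"]
        for region, rmask in region_masks.items():
            analysis = cregions.combine_exclusions(maskset, rmask)
            for metric, m in (
                ("thickness_um", thickness_maps[visit]),
                ("cvi", cvi_maps_out[visit]),
            ):
                rm = cregions.regional_mean(m, analysis)
                rows.append(
                    {
                        "patient_id": vol.patient_id,
                        "eye_id": vol.eye_id,
                        "mnv_type": vol.mnv_type,
                        "visit": visit,
                        "region": region,
                        "metric": metric,
                        "value": rm.value,
                        "n_pixels": rm.n_pixels,
                        "eligible": eligible if metric == "cvi" else True,
                    }
                )
    records = pd.DataFrame(rows)
    thresholds = {v: per_visit[v]["threshold"] for v in per_visit}
    return EyeQuantification(
        records=records,
        thickness_maps=thickness_maps,
        cvi_maps=cvi_maps_out,
        surfaces={v: per_visit[v]["surfaces"] for v in per_visit},
        transforms=transforms,
        thresholds=thresholds,
        eligible=eligible,
        excluded_fraction=excluded_fraction,
        log=log,
    )


def run_analyze(
    config: PipelineConfig, records: pd.DataFrame
) -> tuple[dict[str, pd.DataFrame], str]:
    """Build the six-table longitudinal report from a measurement table."""
    if records.empty:
        raise ValueError("empty measurement table")
    required = {"patient_id", "eye_id", "mnv_type", "visit", "region", "metric", "value"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"measurement table missing columns: {sorted(missing)}")
    if records["eye_id"].nunique() < 2:
        raise ValueError("need at least 2 eyes to analyze")
    tables = summarize_tables(records, correction=config.stats_correction)  # type: ignore[arg-type]
    titles = {
        "all_eyes_pretreatment_to_exudation": "Pretreatment to day of exudation, all eyes",
        "by_type_pretreatment_to_exudation": "Increase pretreatment to exudation, by MNV type",
        "all_eyes_exudation_to_post_treatment": "Day of exudation to post-treatment, all eyes",
        "by_type_exudation_to_post_treatment": "Decrease exudation to post-treatment, by MNV type",
        "all_eyes_pretreatment_to_post_treatment": "Pretreatment to post-treatment, all eyes",
        "by_type_pretreatment_to_post_treatment": "Change pretreatment to post-treatment, by MNV type",
    }
    report = "\n".join(format_table(tables[k], titles.get(k, k)) for k in tables)
    return tables, report
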