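"""End-to-end pipeline: simulate → segment → estimate → validate → thermal.

One config object (YAML-serialisable, lossless round-trip) drives the
whole run; every stage writes its outputs under the run directory and
registers them, with SHA-256 checksums, in a manifest.  The manifest is
fully deterministic for a fixed config + seed — timestamps in it are
data timestamps, not wall-clock — so two runs of the same config are
byte-identical, checksums included.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd

from . import __version__
from .core import CameraGeometry, CropWindow, PhenoroofError
from .height import export_point_cloud, pixel_heights, summarize_heights
from .io import (
    read_scan,
    read_sensor_suite,
    write_mask_png,
    write_scan,
    write_sensor_suite,
)
from .segmentation import render_mask, segment_scan
from .synthetic import SensorSimSpec, generate_scene, generate_sensor_suite, tiered_scene_spec
from .thermal import climate_table, cooling_effect, diurnal_cooling, substrate_attenuation
from .validation import validate_run

__all__ = ["RunConfig", "CropPlan", "ThermalPlan", "RunManifest",
           "PipelineStageError", "run_pipeline", "demo_config"]


class PipelineStageError(PhenoroofError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class CropPlan:
    """Weekly scan campaign for one monitored crop."""

    name: str
    weekly_heights_cm: List[float]
    first_scan: str = "2022-08-05T10:00:00"
    fph_offset_days: List[int] = dc_field(default_factory=list)

    def to_dict(self) -> dict:
        return {"name": self.name,
                "weekly_heights_cm": list(self.weekly_heights_cm),
                "first_scan": self.first_scan,
                "fph_offset_days": list(self.fph_offset_days)}

    @classmethod
    def from_dict(cls, d: dict) -> "CropPlan":
        return cls(**d)


@dataclass
class ThermalPlan:
    """Synthetic sensor campaign: per-crop cooling offsets vs control."""

    start: str = "2022-08-01T00:00:00"
    days: int = 14
    # crop → (offset at 15 cm, offset at 60 cm, substrate attenuation), °C
    crop_offsets_C: Dict[str, List[float]] = dc_field(default_factory=dict)
    noise_sd_C: float = 0.2
    missing_fraction: float = 0.0
    substrate_lag_hours: float = 2.0
    substrate_damping: float = 0.5

    @property
    def end(self) -> str:
        return str(pd.Timestamp(self.start) + pd.Timedelta(days=self.days))

    def to_dict(self) -> dict:
        return {"start": self.start, "days": self.days,
                "crop_offsets_C": {k: list(v) for k, v in self.crop_offsets_C.items()},
                "noise_sd_C": self.noise_sd_C,
                "missing_fraction": self.missing_fraction,
                "substrate_lag_hours": self.substrate_lag_hours,
                "substrate_damping": self.substrate_damping}

    @classmethod
    def from_dict(cls, d: dict) -> "ThermalPlan":
        return cls(**d)


@dataclass
class RunConfig:
    """Single source of every run parameter."""

    geometry: CameraGeometry = dc_field(default_factory=CameraGeometry)
    crop_window: CropWindow = dc_field(default_factory=lambda: CropWindow(8, 8, 8, 8))
    invert_polarity: bool = False
    morph_iterations: int = 1
    iph_percentile: int = 98
    report_percentiles: List[int] = dc_field(default_factory=lambda: [98, 99, 100])
    completeness_min: float = 0.8
    image_width_px: int = 240
    image_height_px: int = 240
    disparity_noise_sd_px: float = 0.5
    shadow_fraction: float = 0.05
    occlusion_fraction: float = 0.02
    disparity_fmt: str = "npy"
    crops: List[CropPlan] = dc_field(default_factory=list)
    thermal: ThermalPlan = dc_field(default_factory=ThermalPlan)
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "geometry": self.geometry.to_dict(),
            "crop_window": self.crop_window.to_dict(),
            "invert_polarity": self.invert_polarity,
            "morph_iterations": self.morph_iterations,
            "iph_percentile": self.iph_percentile,
            "report_percentiles": list(self.report_percentiles),
            "completeness_min": self.completeness_min,
            "image_width_px": self.image_width_px,
            "image_height_px": self.image_height_px,
            "disparity_noise_sd_px": self.disparity_noise_sd_px,
            "shadow_fraction": self.shadow_fraction,
            "occlusion_fraction": self.occlusion_fraction,
            "disparity_fmt": self.disparity_fmt,
            "crops": [c.to_dict() for c in self.crops],
            "thermal": self.thermal.to_dict(),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["geometry"] = CameraGeometry.from_dict(d["geometry"])
        d["crop_window"] = CropWindow.from_dict(d["crop_window"])
        d["crops"] = [CropPlan.from_dict(c) for c in d.get("crops", [])]
        d["thermal"] = ThermalPlan.from_dict(d["thermal"])
        return cls(**d)


@dataclass
class RunManifest:
    """Deterministic record of one pipeline run."""

    config: dict
    version: str
    stages: List[dict] = dc_field(default_factory=list)

    def add_stage(self, name: str, inputs: Dict[str, str],
                  outputs: Dict[str, str], warnings: List[str],
                  counts: Dict[str, int]) -> None:
        self.stages.append({"stage": name, "inputs": inputs, "outputs": outputs,
                            "warnings": warnings, "counts": counts})

    def warnings(self) -> List[str]:
        return [w for s in self.stages for w in s["warnings"]]

    def to_json(self) -> str:
        return json.dumps({"config": self.config, "version": self.version,
                           "stages": self.stages}, indent=2, sort_keys=True)

    def write(self, path) -> Path:
        path = Path(path)
        path.write_text(self.to_json())
        return path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _checksum_map(root: Path, paths) -> Dict[str, str]:
    return {str(Path(p).relative_to(root)): _sha256(Path(p)) for p in sorted(map(str, paths))}


def demo_config(seed: int = 0) -> RunConfig:
    """A compact two-crop, 14-day demonstration campaign.

    A tall okra-like crop (75→160 cm over four weekly scans) and a short
    bush-bean-like crop (15→33 cm), plus a control / three crop beds /
    substrates / met sensor suite with cooling offsets in the range
    field studies report (≈0.5–2 °C).
    """
    return RunConfig(
        crops=[
            CropPlan("okra", [75.0, 100.0, 130.0, 160.0],
                     first_scan="2022-08-05T10:00:00",
                     fph_offset_days=[0, 1, -1, 0]),
            CropPlan("bushbean", [15.0, 22.0, 28.0, 33.0],
                     first_scan="2022-08-05T11:00:00",
                     fph_offset_days=[0, 0, 1, 0]),
        ],
        thermal=ThermalPlan(
            start="2022-08-01T00:00:00", days=14,
            crop_offsets_C={"beet": [2.0, 1.2, 0.9],
                            "zucchini": [1.9, 1.0, 0.8],
                            "celery": [1.0, 0.6, 0.5]},
        ),
        seed=seed,
    )


def _stage_simulate(cfg: RunConfig, outdir: Path, manifest: RunManifest) -> dict:
    scans_dir = outdir / "scans"
    sensors_dir = outdir / "sensors"
    outputs, warnings = [], []
    field_rows = []
    scan_index = []
    base = int(cfg.seed) % (2**31 - 1)
    i = 0
    for plan in cfg.crops:
        t0 = pd.Timestamp(plan.first_scan)
        for week, h in enumerate(plan.weekly_heights_cm):
            spec = tiered_scene_spec(
                h, cfg.geometry,
                width_px=cfg.image_width_px, height_px=cfg.image_height_px,
                disparity_noise_sd_px=cfg.disparity_noise_sd_px,
                shadow_fraction=cfg.shadow_fraction,
                occlusion_fraction=cfg.occlusion_fraction,
                seed=(base + 17 * i + 1) % (2**31 - 1),
                acquired_at=str(t0 + pd.Timedelta(weeks=week)),
                label=plan.name,
            )
            scan = generate_scene(spec)
            stem = f"{plan.name}_w{week}"
            paths = write_scan(scan, scans_dir, stem, disparity_fmt=cfg.disparity_fmt)
            outputs.extend(paths.values())
            offs = plan.fph_offset_days[week] if week < len(plan.fph_offset_days) else 0
            field_rows.append({
                "date": (pd.Timestamp(spec.acquired_at).normalize()
                         + pd.Timedelta(days=offs)).date().isoformat(),
                "crop": plan.name, "fph_cm": h})
            scan_index.append({"stem": stem, "crop": plan.name,
                               "acquired_at": spec.acquired_at})
            i += 1
    field_log = outdir / "field_log.csv"
    pd.DataFrame(field_rows).to_csv(field_log, index=False)
    index_path = outdir / "scan_index.csv"
    pd.DataFrame(scan_index).to_csv(index_path, index=False)
    outputs += [field_log, index_path]

    tp = cfg.thermal
    specs: Dict[str, SensorSimSpec] = {
        "control": SensorSimSpec(tp.start, tp.end, 15, role="control",
                                 noise_sd_C=tp.noise_sd_C,
                                 missing_fraction=tp.missing_fraction,
                                 seed=(base + 9001) % (2**31 - 1)),
    }
    j = 0
    for crop, (off15, off60, atten) in tp.crop_offsets_C.items():
        common = dict(noise_sd_C=tp.noise_sd_C, missing_fraction=tp.missing_fraction)
        specs[f"{crop}_15cm"] = SensorSimSpec(
            tp.start, tp.end, 15, cooling_offset_C=off15, role="crop-15cm",
            crop=crop, include_humidity=True,
            seed=(base + 9101 + j) % (2**31 - 1), **common)
        specs[f"{crop}_60cm"] = SensorSimSpec(
            tp.start, tp.end, 15, cooling_offset_C=off60, role="crop-60cm",
            crop=crop, include_humidity=True,
            seed=(base + 9201 + j) % (2**31 - 1), **common)
        specs[f"{crop}_substrate"] = SensorSimSpec(
            tp.start, tp.end, 10, cooling_offset_C=off15 + atten, role="substrate",
            crop=crop, substrate_lag_hours=tp.substrate_lag_hours,
            substrate_damping=tp.substrate_damping,
            seed=(base + 9301 + j) % (2**31 - 1), **common)
        j += 1
    met_defs = {"temperature": dict(diurnal_mean_C=23.0, diurnal_amplitude_C=8.0),
                "relative_humidity": dict(diurnal_mean_C=65.0, diurnal_amplitude_C=15.0,
                                          peak_hour=4.0),
                "dew_point": dict(diurnal_mean_C=14.0, diurnal_amplitude_C=3.0),
                "wind": dict(diurnal_mean_C=2.0, diurnal_amplitude_C=1.2, clip_min=0.0),
                "par": dict(diurnal_mean_C=500.0, diurnal_amplitude_C=600.0,
                            peak_hour=13.0, clip_min=0.0)}
    for k, (var, kw) in enumerate(met_defs.items()):
        specs[f"met_{var}"] = SensorSimSpec(
            tp.start, tp.end, 15, role="met", variable=var,
            noise_sd_C=tp.noise_sd_C, missing_fraction=tp.missing_fraction,
            seed=(base + 9401 + k) % (2**31 - 1), **kw)
    suite = generate_sensor_suite(specs)
    manifest_path = write_sensor_suite(suite, sensors_dir)
    outputs += list(sensors_dir.glob("*.csv"))

    manifest.add_stage("simulate", {}, _checksum_map(outdir, outputs), warnings,
                       {"n_scans": i, "n_stations": len(suite)})
    return {"scans_dir": scans_dir, "sensors_dir": sensors_dir,
            "field_log": field_log, "scan_index": index_path}


def _stage_segment(cfg: RunConfig, outdir: Path, manifest: RunManifest, ctx: dict) -> dict:
    masks_dir = outdir / "masks"
    index = pd.read_csv(ctx["scan_index"])
    inputs, outputs, warnings = [], [], []
    masks = {}
    cropped = {}
    counts = {"foreground_px": 0}
    for _, row in index.iterrows():
        stem = row["stem"]
        png = ctx["scans_dir"] / f"{stem}.png"
        side = ctx["scans_dir"] / f"{stem}_disparity.{'npy' if cfg.disparity_fmt == 'npy' else 'csv'}"
        scan = read_scan(png, side, cfg.geometry, row["acquired_at"], label=row["crop"])
        inputs += [png, side]
        mask, crop_scan = segment_scan(scan, cfg.crop_window,
                                       invert=cfg.invert_polarity,
                                       iterations=cfg.morph_iterations)
        out = write_mask_png(render_mask(mask.mask), masks_dir / f"{stem}_mask.png")
        outputs.append(out)
        masks[stem] = mask
        cropped[stem] = crop_scan
        counts["foreground_px"] += mask.foreground_count
    manifest.add_stage("segment", _checksum_map(outdir, inputs),
                       _checksum_map(outdir, outputs), warnings, counts)
    return {**ctx, "masks": masks, "cropped": cropped, "masks_dir": masks_dir}


def _stage_estimate(cfg: RunConfig, outdir: Path, manifest: RunManifest, ctx: dict) -> dict:
    heights_dir = outdir / "heights"
    heights_dir.mkdir(parents=True, exist_ok=True)
    warnings, rows, summaries = [], [], []
    counts = {"n_invalid_disparity": 0, "n_out_of_range": 0}
    percentiles = sorted(set(range(95, 101)) | set(cfg.report_percentiles)
                         | {cfg.iph_percentile})
    ply_paths = []
    for stem, mask in ctx["masks"].items():
        field = pixel_heights(ctx["cropped"][stem], mask)
        counts["n_invalid_disparity"] += field.n_invalid_disparity
        counts["n_out_of_range"] += field.n_out_of_range
        if field.n_out_of_range:
            warnings.append(
                f"{stem}: {field.n_out_of_range} foreground pixels outside the "
                "depth validity window (canopy near the sensor limit?)")
        summary = summarize_heights(field, percentiles=percentiles,
                                    iph_percentile=cfg.iph_percentile)
        summaries.append(summary)
        rows.append(summary.row())
        ply = heights_dir / f"{stem}.ply"
        export_point_cloud(field, ply)
        ply_paths.append(ply)
    csv_path = heights_dir / "summaries.csv"
    pd.DataFrame(rows).to_csv(csv_path, index=False, float_format="%.6f")
    manifest.add_stage("estimate", {}, _checksum_map(outdir, [csv_path] + ply_paths),
                       warnings, counts)
    return {**ctx, "summaries": summaries, "summaries_csv": csv_path}


def _stage_validate(cfg: RunConfig, outdir: Path, manifest: RunManifest, ctx: dict) -> dict:
    field_log = pd.read_csv(ctx["field_log"])
    report = validate_run(ctx["summaries"], field_log,
                          percentiles=tuple(cfg.report_percentiles))
    path = outdir / "validation_report.csv"
    report.to_csv(path)
    warnings = [f"unmatched scan {s.label} at {s.scan_time}" for s in report.unmatched]
    manifest.add_stage("validate", _checksum_map(outdir, [ctx["field_log"]]),
                       _checksum_map(outdir, [path]), warnings,
                       {"n_matched": sum(len(r) for r in report.records.values()),
                        "n_unmatched": len(report.unmatched)})
    return {**ctx, "report": report, "report_csv": path}


def _stage_thermal(cfg: RunConfig, outdir: Path, manifest: RunManifest, ctx: dict) -> dict:
    thermal_dir = outdir / "thermal"
    thermal_dir.mkdir(parents=True, exist_ok=True)
    suite = read_sensor_suite(ctx["sensors_dir"])
    by_role: Dict[str, list] = {}
    for s in suite:
        by_role.setdefault(s.role, []).append(s)
    control = by_role.get("control", [None])[0]
    if control is None:
        raise PhenoroofError("suite has no control station")
    warnings, outputs = [], []

    cool_rows, atten_rows = [], []
    for role in ("crop-15cm", "crop-60cm"):
        for s in by_role.get(role, []):
            cs = cooling_effect(control, s, cfg.completeness_min)
            cool_rows.append(cs.row())
    sub_by_crop = {s.crop: s for s in by_role.get("substrate", [])}
    for s in by_role.get("crop-15cm", []):
        sub = sub_by_crop.get(s.crop)
        if sub is None:
            warnings.append(f"no substrate station for crop {s.crop}")
            continue
        atten_rows.append(substrate_attenuation(sub, s, cfg.completeness_min).row())
    cooling_csv = thermal_dir / "cooling_summary.csv"
    pd.DataFrame(cool_rows).to_csv(cooling_csv, index=False, float_format="%.6f")
    atten_csv = thermal_dir / "substrate_attenuation.csv"
    pd.DataFrame(atten_rows).to_csv(atten_csv, index=False, float_format="%.6f")
    outputs += [cooling_csv, atten_csv]

    months = sorted({str(p) for s in suite
                     for p in s.values.index.to_period("M").unique()})
    diurnal_rows = []
    for month in months:
        for s in by_role.get("crop-15cm", []):
            deltas = diurnal_cooling(control, s, month)
            for hour, v in deltas.items():
                diurnal_rows.append({"month": month, "crop": s.crop, "hour": hour,
                                     "cooling_C": v})
    diurnal_csv = thermal_dir / "diurnal_cooling.csv"
    pd.DataFrame(diurnal_rows).to_csv(diurnal_csv, index=False, float_format="%.6f")
    outputs.append(diurnal_csv)

    climate_csv = thermal_dir / "climate_table.csv"
    climate_table(by_role.get("met", []), cfg.completeness_min).to_csv(
        climate_csv, float_format="%.6f")
    outputs.append(climate_csv)

    manifest.add_stage("thermal", {}, _checksum_map(outdir, outputs), warnings,
                       {"n_stations": len(suite), "n_months": len(months)})
    return {**ctx, "cooling_csv": cooling_csv}


_STAGES = [("simulate", _stage_simulate), ("segment", _stage_segment),
           ("estimate", _stage_estimate), ("validate", _stage_validate),
           ("thermal", _stage_thermal)]


def run_pipeline(config: RunConfig, outdir) -> RunManifest:
    """Execute all stages in order; halt naming the failing stage.

    Writes every stage output plus ``manifest.json`` under ``outdir``
    and returns the manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict(), version=__version__)
    ctx: dict = {}
    for name, fn in _STAGES:
        try:
            if name == "simulate":
                ctx = fn(config, outdir, manifest)
            else:
                ctx = fn(config, outdir, manifest, ctx)
        except PipelineStageError:
            raise
        except Exception as exc:
            raise PipelineStageError(name, exc) from exc
    manifest.write(outdir / "manifest.json")
    return manifest
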