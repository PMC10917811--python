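"""End-to-end orchestration: simulate -> segment -> quantify -> stats.

A single YAML config drives a reproducible run; each stage can also be
invoked piecewise through the library or the CLI. Outputs are plain CSV/JSON
with a run manifest recording the config hash, seed, per-stage counts and QC
tallies so a run is auditable without re-executing it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .calibration import (
    CalibrationCurve,
    PROGESTERONE_MOLAR_MASS,
    p4_equivalent,
    to_source_concentration,
)
from .core import ConfigError, ImageField, PipelineError
from .layout import PlateLayout
from .quantify import aggregate, measure_cells, normalize
from .segment import SegmentationParams, make_ring, segment_nuclei, shrink_labels
from .synthdata import OpticsSpec, ResponseModel, SceneSpec, simulate_plate, write_plate

log = logging.getLogger(__name__)

SCHEMA_VERSION = "nuctrans-1"


def load_fields(manifest_path, base_dir=None) -> list[ImageField]:
    """Read a plate back from a manifest CSV into ImageField objects."""
    manifest_path = Path(manifest_path)
    base = Path(base_dir) if base_dir is not None else manifest_path.parent
    manifest = pd.read_csv(manifest_path)
    fields = []
    for (plate, well, fidx), grp in manifest.groupby(
        ["plate", "well", "field"], sort=True
    ):
        channels = {
            row.channel: tifffile.imread(base / row.path).astype(float)
            for row in grp.itertuples()
        }
        fields.append(
            ImageField(channels=channels, plate=plate, well=well, field_index=int(fidx))
        )
    return fields


@dataclass
class PlateAnalysis:
    """Per-cell, per-well and per-sample tables plus QC tallies."""

    cells: pd.DataFrame
    wells: pd.DataFrame
    samples: pd.DataFrame
    qc: dict = field(default_factory=dict)


def analyze_fields(
    fields,
    layout: PlateLayout,
    seg_params: SegmentationParams | None = None,
    ring_width: int = 4,
    gap: int = 2,
    background_mode: str = "field_median",
    min_cells_per_well: int = 50,
) -> PlateAnalysis:
    """Segment and quantify a set of fields against a plate layout.

    Rings are constructed from the full nucleus mask; the nuclear mean is
    measured over the mask shrunk by ``seg_params.shrink_px`` so the
    blur-mixed boundary shell contaminates neither compartment. The default
    ``field_median`` background mode removes the camera offset, which would
    otherwise bias every ratio toward 1.
    """
    seg_params = seg_params or SegmentationParams()
    all_cells = []
    tallies = {"n_fields": 0, "n_cells": 0, "n_dropped_low_ring": 0, "n_empty_fields": 0}
    for fld in fields:
        nuclei = segment_nuclei(fld, params=seg_params)
        rings = make_ring(nuclei, ring_width=ring_width, gap=gap)
        nuclei_m = shrink_labels(nuclei, seg_params.shrink_px)
        cells, qc = measure_cells(fld, nuclei_m, rings, background_mode=background_mode)
        tallies["n_fields"] += 1
        tallies["n_cells"] += len(cells)
        tallies["n_dropped_low_ring"] += qc["n_dropped_low_ring"]
        if not len(cells):
            tallies["n_empty_fields"] += 1
        all_cells.append(cells)
    cells = (
        pd.concat(all_cells, ignore_index=True)
        if all_cells
        else pd.DataFrame()
    )
    wells = aggregate(cells, layout, min_cells_per_well=min_cells_per_well)
    samples = normalize(wells, layout)
    tallies["n_low_count_wells"] = int(wells["low_count"].sum()) if len(wells) else 0
    return PlateAnalysis(cells=cells, wells=wells, samples=samples, qc=tallies)


@dataclass
class RunManifest:
    """Provenance record for one pipeline run."""

    version: str
    seed: int
    config_hash: str
    status: str
    outputs: list[str] = field(default_factory=list)
    counts: dict = field(default_factory=dict)
    failed_stage: str | None = None
    timestamp: str = ""

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


_KNOWN_STAGES = ("simulate", "analyze", "calibrate", "screen")
_KNOWN_KEYS = {
    "seed",
    "out",
    "stages",
    "layout",
    "scene",
    "optics",
    "model",
    "segmentation",
    "quantify",
    "calibration",
    "screen",
}


def _build(cls, cfg: dict | None):
    try:
        return cls(**(cfg or {}))
    except TypeError as exc:
        raise ConfigError(f"bad {cls.__name__} config: {exc}") from exc


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text())
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping or a YAML file path")
    return config


def run_pipeline(config, seed: int | None = None, out_dir=None) -> RunManifest:
    """Execute the configured stages in order; see docs/methods.md.

    The config is validated before any computation (unknown keys/stages and
    layout violations fail fast). On a mid-run stage failure, outputs written
    so far are retained and the manifest marks the failure point before the
    error is re-raised as :class:`PipelineError`.
    """
    cfg = _load_config(config)
    unknown = set(cfg) - _KNOWN_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    stages = list(cfg.get("stages", ["simulate", "analyze"]))
    bad = [s for s in stages if s not in _KNOWN_STAGES]
    if bad:
        raise ConfigError(f"unknown stages: {bad}; valid: {list(_KNOWN_STAGES)}")

    seed = int(cfg.get("seed", 0) if seed is None else seed)
    out = Path(out_dir if out_dir is not None else cfg.get("out", "nuctrans_run"))

    layout_cfg = cfg.get("layout")
    if layout_cfg is None:
        raise ConfigError("config must provide a layout (mapping or path)")
    layout = (
        PlateLayout.from_yaml(layout_cfg)
        if isinstance(layout_cfg, (str, Path))
        else PlateLayout.from_dict(layout_cfg)
    )
    report = layout.validate()
    if not report.ok:
        raise ConfigError("layout invalid: " + "; ".join(report.violations))
    for w in report.warnings:
        log.warning("layout: %s", w)

    scene = _build(SceneSpec, cfg.get("scene"))
    optics = _build(OpticsSpec, cfg.get("optics"))
    model = _build(ResponseModel, cfg.get("model"))
    seg_cfg = dict(cfg.get("segmentation") or {})
    ring_width = int(seg_cfg.pop("ring_width", 4))
    gap = int(seg_cfg.pop("gap", 2))
    seg_params = _build(SegmentationParams, seg_cfg)
    quant_cfg = dict(cfg.get("quantify") or {})

    config_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()
    manifest = RunManifest(
        version=__version__,
        seed=seed,
        config_hash=config_hash,
        status="running",
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    out.mkdir(parents=True, exist_ok=True)

    def _emit(df: pd.DataFrame, name: str) -> None:
        path = out / name
        with open(path, "w") as fh:
            fh.write(f"# schema: {SCHEMA_VERSION}\n")
            df.to_csv(fh, index=False)
        manifest.outputs.append(name)

    analysis: PlateAnalysis | None = None
    current = ""
    try:
        fields = None
        if "simulate" in stages:
            current = "simulate"
            sim = simulate_plate(layout, scene, optics, model, rng_seed=seed)
            img_dir = out / "images"
            write_plate(sim, img_dir)
            manifest.outputs += ["images/manifest.csv", "images/ground_truth.csv"]
            manifest.counts["simulate"] = {
                "n_fields": len(sim.fields),
                "n_cells_truth": int(len(sim.ground_truth)),
            }
            fields = load_fields(img_dir / "manifest.csv")
        if "analyze" in stages:
            current = "analyze"
            if fields is None:
                images = quant_cfg.get("images") or (out / "images")
                fields = load_fields(Path(images) / "manifest.csv")
            analysis = analyze_fields(
                fields,
                layout,
                seg_params=seg_params,
                ring_width=ring_width,
                gap=gap,
                background_mode=quant_cfg.get("background_mode", "none"),
                min_cells_per_well=int(quant_cfg.get("min_cells_per_well", 50)),
            )
            _emit(analysis.cells, "cells.csv")
            _emit(analysis.wells, "wells.csv")
            _emit(analysis.samples, "samples.csv")
            manifest.counts["analyze"] = analysis.qc
        curve = None
        if "calibrate" in stages:
            current = "calibrate"
            if analysis is None:
                raise PipelineError("calibrate stage requires analyze outputs")
            cal_cfg = cfg.get("calibration") or {}
            standards = cal_cfg.get("standards")
            if not standards:
                raise ConfigError("calibration.standards (sample -> nM) required")
            rows = analysis.samples.set_index("sample")
            concs, ys = [], []
            for sample, conc in standards.items():
                if sample not in rows.index:
                    raise ConfigError(f"standard sample {sample!r} not in results")
                concs.append(float(conc))
                ys.append(float(rows.loc[sample, "y"]))
            curve = CalibrationCurve.fit(
                concs, ys, fix_intercept_at_1=bool(cal_cfg.get("fix_intercept_at_1", True))
            )
            curve.to_json(out / "calibration.json")
            manifest.outputs.append("calibration.json")
            manifest.counts["calibrate"] = {"n_standards": len(concs)}
        if "screen" in stages:
            current = "screen"
            if analysis is None:
                raise PipelineError("screen stage requires analyze outputs")
            scr = cfg.get("screen") or {}
            if curve is None:
                calib_path = scr.get("calibration")
                if not calib_path:
                    raise ConfigError(
                        "screen stage needs a calibrate stage or screen.calibration path"
                    )
                curve = CalibrationCurve.from_json(Path(calib_path))
            factor = float(scr.get("concentration_factor", 200.0))
            molar_mass = float(scr.get("molar_mass", PROGESTERONE_MOLAR_MASS))
            p4rows = []
            for row in analysis.samples.itertuples():
                if row.sample in (cfg.get("calibration") or {}).get("standards", {}):
                    continue
                if bool(analysis.wells.loc[
                    analysis.wells["sample"] == row.sample, "is_vehicle"
                ].iloc[0]):
                    continue
                assay_nm = p4_equivalent(row.y, curve)
                res = to_source_concentration(
                    assay_nm, factor, molar_mass, sample=row.sample, y=row.y
                )
                p4rows.append(asdict(res))
            _emit(pd.DataFrame(p4rows), "p4eq.csv")
            manifest.counts["screen"] = {"n_samples": len(p4rows)}
        manifest.status = "completed"
    except Exception as exc:
        manifest.status = "failed"
        manifest.failed_stage = current
        manifest.to_json(out / "manifest.json")
        if isinstance(exc, (ConfigError, PipelineError)):
            raise
        raise PipelineError(f"stage {current!r} failed: {exc}") from exc

    for name in manifest.outputs:
        p = out / name
        if not p.exists() or p.stat().st_size == 0:
            manifest.status = "failed"
            manifest.failed_stage = "finalize"
            break
    manifest.to_json(out / "manifest.json")
    return manifest


def zprime_from_wells(
    wells: pd.DataFrame, pos_sample: str, neg_sample: str
) -> float:
    """Z'-factor between two samples' replicate well values."""
    from .qc import z_prime

    pos = wells.loc[wells["sample"] == pos_sample, "well_value"].to_numpy()
    neg = wells.loc[wells["sample"] == neg_sample, "well_value"].to_numpy()
    return z_prime(pos, neg)
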