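"""Configuration-driven pipeline runs with provenance.

A run config is a single YAML/JSON mapping with a mandatory ``seed`` and
``out_dir`` plus one section per requested stage.  All sections are
validated before any computation; stages execute in a fixed order and every
output directory receives a ``provenance.json`` naming the config hash, the
seed and the package version, so identical config + seed reproduce
identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .confocal_cluster import quantify_roi
from .datatypes import MembraneROI
from .particle_analysis import (
    assign_membrane_domains,
    classify_particle_groups,
    groups_table,
    iem_profile_summary,
    link_particles,
    particles_per_cluster_gradient,
)
from .polarity_metrics import aggregate_polarity, apical_lateral_ratio
from .stats_report import summarize
from .synthetic_data import (
    FieldSimParams,
    MembraneFace,
    StackSimParams,
    simulate_membrane_stack,
    simulate_particle_field,
)

STAGE_ORDER = (
    "simulate_stack",
    "simulate_particles",
    "confocal_quant",
    "frl_quant",
    "iem_quant",
    "polarity",
    "report",
)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def load_config(path: Union[str, Path]) -> dict:
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def validate_config(config: dict) -> None:
    """Validate every stage section against stage preconditions up front."""
    if "out_dir" not in config:
        raise ValueError("config needs an out_dir")
    unknown = set(config) - set(STAGE_ORDER) - {"seed", "out_dir"}
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    if "confocal_quant" in config:
        c = config["confocal_quant"]
        lo = c.get("min_side_px", 5)
        hi = c.get("max_side_px", 9)
        if lo > hi:
            raise ValueError("confocal_quant: min_side_px must not exceed max_side_px")
    if "simulate_stack" in config:
        _stack_params(config["simulate_stack"], config.get("seed", 0))  # raises on bad values
    if "simulate_particles" in config:
        _field_params(config["simulate_particles"], config.get("seed", 0))
    for stage in ("frl_quant", "iem_quant"):
        if stage in config and config[stage].get("dmax_nm", 55.0) <= 0:
            raise ValueError(f"{stage}: dmax_nm must be positive")


def _stack_params(section: dict, seed: int) -> StackSimParams:
    faces = tuple(MembraneFace(**f) for f in section.get("membrane_faces", []))
    kwargs = {k: v for k, v in section.items() if k != "membrane_faces"}
    if "shape_zyx" in kwargs:
        kwargs["shape_zyx"] = tuple(kwargs["shape_zyx"])
    if "voxel_size_xyz_um" in kwargs:
        kwargs["voxel_size_xyz_um"] = tuple(kwargs["voxel_size_xyz_um"])
    kwargs.setdefault("seed", seed)
    return StackSimParams(membrane_faces=faces, **kwargs)


def _field_params(section: dict, seed: int) -> FieldSimParams:
    kwargs = dict(section)
    if "field_size_um" in kwargs:
        kwargs["field_size_um"] = tuple(kwargs["field_size_um"])
    kwargs.setdefault("seed", seed)
    return FieldSimParams(**kwargs)


def run_pipeline(config: dict) -> dict:
    """Execute the configured stages in order; return a result bundle.

    Any stage failure aborts the run with the failing stage named.
    """
    validate_config(config)
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    bundle: dict = {"out_dir": str(out_dir)}

    for stage in STAGE_ORDER:
        if stage not in config:
            continue
        try:
            runner = _RUNNERS[stage]
            bundle[stage] = runner(config[stage], seed, out_dir, bundle)
        except Exception as exc:  # noqa: BLE001 - stage name must surface
            raise StageError(stage, exc) from exc

    provenance = {
        "config": config,
        "config_hash": config_hash(config),
        "seed": seed,
        "package_version": __version__,
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
    }
    (out_dir / "provenance.json").write_text(json.dumps(provenance, indent=1, default=str))
    bundle["provenance"] = provenance
    return bundle


# ---------------------------------------------------------------------------
# stage runners
# ---------------------------------------------------------------------------

def _run_simulate_stack(section: dict, seed: int, out_dir: Path, bundle: dict) -> dict:
    params = _stack_params(section, seed)
    stack, truth = simulate_membrane_stack(params)
    path = out_dir / "stack.tif"
    io.write_stack(
        path,
        stack,
        truth={
            "planted_counts": list(truth.planted_counts),
            "face_areas_um2": list(truth.face_areas_um2),
            "planted_centers_um": [[list(c) for c in face] for face in truth.planted_centers_um],
        },
    )
    return {"stack_path": str(path), "planted_counts": list(truth.planted_counts)}


def _run_simulate_particles(section: dict, seed: int, out_dir: Path, bundle: dict) -> dict:
    params = _field_params(section, seed)
    particles, truth = simulate_particle_field(params)
    csv_path = out_dir / "particles.csv"
    geom_path = out_dir / "particles_geometry.json"
    io.write_particles(csv_path, particles, geom_path)
    truth_path = out_dir / "particles_truth.json"
    truth_path.write_text(
        json.dumps(
            {
                "class_fractions_percent": truth.class_fractions,
                "retained_class_fractions_percent": truth.retained_class_fractions,
                "band_counts": truth.band_counts,
                "n_labels": int(len(truth.labels)),
                "n_retained": int(truth.labels["retained"].sum()),
            },
            indent=1,
            default=str,
        )
    )
    return {"particles_path": str(csv_path), "geometry_path": str(geom_path), "truth_path": str(truth_path)}


def _run_confocal_quant(section: dict, seed: int, out_dir: Path, bundle: dict) -> dict:
    stack_path = section.get("stack") or bundle.get("simulate_stack", {}).get("stack_path")
    if stack_path is None:
        raise ValueError("confocal_quant needs a stack path or a simulate_stack stage")
    stack = io.read_stack(stack_path)
    if "rois" in section:
        rois = io.read_rois(section["rois"])
    else:
        # default: one full-stack ROI projected along z
        nz, ny, nx = stack.shape
        rois = [MembraneROI(id="full", bounds_zyx=((0, nz), (0, ny), (0, nx)), projection_axis="z")]
    kwargs = {
        k: section[k]
        for k in ("min_side_px", "max_side_px", "n_cap", "area_threshold", "low_contrast_percentile", "drop_low_contrast")
        if k in section
    }
    summaries, call_rows = [], []
    for roi in rois:
        result, calls = quantify_roi(stack, roi, **kwargs)
        summaries.append(dataclasses.asdict(result))
        for c in calls:
            call_rows.append(
                {
                    "roi": roi.id,
                    "row": c.peak[0],
                    "col": c.peak[1],
                    "side_px": c.side_px,
                    "diameter_um": c.diameter_um,
                    "capped": c.capped,
                    "low_contrast": c.low_contrast,
                }
            )
    summary_df = pd.DataFrame(summaries)
    calls_df = pd.DataFrame(call_rows)
    summary_df.to_csv(out_dir / "confocal_summary.csv", index=False)
    calls_df.to_csv(out_dir / "confocal_calls.csv", index=False)
    return {"summary": summary_df, "calls": calls_df}


def _run_frl_quant(section: dict, seed: int, out_dir: Path, bundle: dict) -> dict:
    csv_path = section.get("particles") or bundle.get("simulate_particles", {}).get("particles_path")
    geom_path = section.get("geometry") or bundle.get("simulate_particles", {}).get("geometry_path")
    if csv_path is None:
        raise ValueError("frl_quant needs a particle CSV or a simulate_particles stage")
    particles = io.read_particles(csv_path, geom_path)
    dmax = section.get("dmax_nm", 55.0)
    band = section.get("band_um", 2.0)
    gold = section.get("gold_diameter_nm", 0.0)
    groups = link_particles(particles, dmax_nm=dmax, gold_diameter_nm=gold)
    classes = classify_particle_groups(groups)
    labels, domain_df = assign_membrane_domains(particles, groups, band_um=band)
    profile = particles_per_cluster_gradient(groups, particles, bin_um=section.get("bin_um", 2.0))
    gt = groups_table(groups)
    gt.to_csv(out_dir / "frl_groups.csv", index=False)
    domain_df.to_csv(out_dir / "frl_domains.csv", index=False)
    profile.to_csv(out_dir / "frl_profile.csv", index=False)
    return {"groups": gt, "classes": classes, "domains": domain_df, "profile": profile}


def _run_iem_quant(section: dict, seed: int, out_dir: Path, bundle: dict) -> dict:
    paths = section.get("particles", [])
    if isinstance(paths, (str, Path)):
        paths = [paths]
    if not paths:
        raise ValueError("iem_quant needs at least one particle CSV")
    groups_per_image = []
    for p in paths:
        particles = io.read_particles(p)
        groups_per_image.append(link_particles(particles, dmax_nm=section.get("dmax_nm", 55.0)))
    summary = iem_profile_summary(groups_per_image, section.get("profile_lengths_um"))
    (out_dir / "iem_summary.json").write_text(json.dumps(summary, indent=1))
    return summary


def _run_polarity(section: dict, seed: int, out_dir: Path, bundle: dict) -> dict:
    stack_path = section.get("stack") or bundle.get("simulate_stack", {}).get("stack_path")
    if stack_path is None:
        raise ValueError("polarity needs a stack path or a simulate_stack stage")
    stack = io.read_stack(stack_path)
    rois = io.read_rois(section["rois"])
    by_cell: dict = {}
    for roi in rois:
        by_cell.setdefault(roi.cell_id or "cell", {})[roi.polarity_label] = roi
    results = []
    for cell_id, parts in sorted(by_cell.items()):
        if "apical" not in parts or "lateral" not in parts:
            raise ValueError(f"cell {cell_id!r} needs one apical and one lateral ROI")
        results.append(apical_lateral_ratio(stack, parts["apical"], parts["lateral"], cell_id=cell_id))
    df = pd.DataFrame(
        [
            {"cell_id": r.cell_id, "apical_mean": r.apical_mean, "lateral_mean": r.lateral_mean, "ratio": r.ratio}
            for r in results
        ]
    )
    df.to_csv(out_dir / "polarity.csv", index=False)
    mean, sd = aggregate_polarity(results)
    return {"table": df, "ratio_mean": mean, "ratio_sd": sd}


def _run_report(section: dict, seed: int, out_dir: Path, bundle: dict) -> dict:
    df = pd.read_csv(section["input"])
    table = summarize(
        df,
        control=section["control"],
        group_col=section.get("group_col", "group"),
        value_col=section.get("value_col", "value"),
        test=section.get("test", "mann_whitney"),
    )
    table.to_csv(out_dir / "report_summary.csv", index=False)
    return {"summary": table}


_RUNNERS = {
    "simulate_stack": _run_simulate_stack,
    "simulate_particles": _run_simulate_particles,
    "confocal_quant": _run_confocal_quant,
    "frl_quant": _run_frl_quant,
    "iem_quant": _run_iem_quant,
    "polarity": _run_polarity,
    "report": _run_report,
}
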