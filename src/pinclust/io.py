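"""File formats: TIFF stacks with JSON sidecars, particle CSVs, ROI files.

Stacks travel as single-channel ImageJ-dialect TIFFs (axes Z, Y, X) with a
JSON sidecar carrying voxel sizes and, for simulated data, the planted
truth.  Particle fields travel as CSVs with columns ``id, x_nm, y_nm`` plus
a geometry JSON describing the analyzed-region polygon and the cell's
apical/basal edges.  All indices in files are 0-based half-open; physical
units are explicit in column names.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import Polygon

from .datatypes import CellAxis, ImageStack, MembraneROI, ParticleSet

PathLike = Union[str, Path]


def _sidecar_path(tiff_path: PathLike) -> Path:
    return Path(str(tiff_path) + ".json")


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        return super().default(o)


# ---------------------------------------------------------------------------
# stacks
# ---------------------------------------------------------------------------

def write_stack(path: PathLike, stack: ImageStack, truth: Optional[dict] = None) -> None:
    """Write a stack as an ImageJ-dialect TIFF plus a JSON sidecar.

    The sidecar records the voxel sizes (authoritative on read) and any
    truth payload supplied by a simulator.
    """
    path = Path(path)
    vz, vy, vx = stack.voxel_size_zyx_um
    tifffile.imwrite(
        path,
        stack.data.astype(np.float32),
        imagej=True,
        resolution=(1.0 / vx, 1.0 / vy),
        metadata={"spacing": vz, "unit": "um", "axes": "ZYX"},
    )
    sidecar = {"voxel_size_zyx_um": list(stack.voxel_size_zyx_um)}
    if truth is not None:
        sidecar["truth"] = truth
    _sidecar_path(path).write_text(json.dumps(sidecar, cls=_NumpyEncoder, indent=1))


def read_stack(
    path: PathLike,
    voxel_size_xyz_um: Optional[Sequence[float]] = None,
) -> ImageStack:
    """Read a single-channel TIFF stack.

    Voxel sizes come from the JSON sidecar when present, then from ImageJ
    TIFF metadata, then from the explicit override; with no source at all
    the read is rejected.  Multi-channel (e.g. RGB) TIFFs are rejected.
    """
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 4 or (data.ndim == 3 and data.shape[-1] in (3, 4) and data.shape[-1] < min(data.shape[:2])):
        raise ValueError(f"{path}: multi-channel TIFF; this pipeline takes single-channel stacks")
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D (Z, Y, X) stack, got shape {data.shape}")

    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        return ImageStack(data=np.asarray(data, dtype=float), voxel_size_zyx_um=tuple(meta["voxel_size_zyx_um"]))
    if voxel_size_xyz_um is not None:
        return ImageStack.from_xyz(np.asarray(data, dtype=float), voxel_size_xyz_um)

    spacing = _imagej_voxel_size(path)
    if spacing is not None:
        return ImageStack(data=np.asarray(data, dtype=float), voxel_size_zyx_um=spacing)
    raise ValueError(
        f"{path}: no voxel calibration found (no sidecar, no ImageJ metadata); "
        "pass voxel_size_xyz_um explicitly"
    )


def _imagej_voxel_size(path: Path) -> Optional[tuple[float, float, float]]:
    with tifffile.TiffFile(path) as tf:
        ij = tf.imagej_metadata
        if not ij or "spacing" not in ij:
            return None
        page = tf.pages[0]
        try:
            xres = page.tags["XResolution"].value
            yres = page.tags["YResolution"].value
            vx = xres[1] / xres[0]
            vy = yres[1] / yres[0]
        except (KeyError, ZeroDivisionError):
            return None
        return (float(ij["spacing"]), float(vy), float(vx))


def read_stack_truth(path: PathLike) -> Optional[dict]:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        return None
    return json.loads(sidecar.read_text()).get("truth")


# ---------------------------------------------------------------------------
# ROIs
# ---------------------------------------------------------------------------

def read_rois(path: PathLike) -> list[MembraneROI]:
    """Read membrane ROIs from JSON.

    Expected form: a list of objects with ``id``, ``bounds_zyx`` (three
    ``[start, stop)`` pairs), ``projection_axis``, and optional
    ``polarity_label`` / ``cell_id``.
    """
    entries = json.loads(Path(path).read_text())
    rois = []
    for e in entries:
        rois.append(
            MembraneROI(
                id=str(e["id"]),
                bounds_zyx=tuple(tuple(int(v) for v in b) for b in e["bounds_zyx"]),
                projection_axis=e.get("projection_axis", "z"),
                polarity_label=e.get("polarity_label", "unspecified"),
                cell_id=e.get("cell_id"),
            )
        )
    return rois


def write_rois(path: PathLike, rois: Sequence[MembraneROI]) -> None:
    payload = [
        {
            "id": r.id,
            "bounds_zyx": [list(b) for b in r.bounds_zyx],
            "projection_axis": r.projection_axis,
            "polarity_label": r.polarity_label,
            "cell_id": r.cell_id,
        }
        for r in rois
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# particles
# ---------------------------------------------------------------------------

def write_particles(csv_path: PathLike, particles: ParticleSet, geometry_path: Optional[PathLike] = None) -> None:
    df = pd.DataFrame({"id": particles.ids, "x_nm": particles.xy_nm[:, 0], "y_nm": particles.xy_nm[:, 1]})
    df.to_csv(csv_path, index=False)
    if geometry_path is not None:
        if particles.region is None or particles.axis is None:
            raise ValueError("particle set has no geometry to write")
        geom = {
            "analyzed_region_nm": list(particles.region.exterior.coords),
            "axis_direction": list(particles.axis.direction),
            "apical_edge_nm": particles.axis.apical_edge_nm,
            "basal_edge_nm": particles.axis.basal_edge_nm,
            "source": particles.source,
        }
        Path(geometry_path).write_text(json.dumps(geom, cls=_NumpyEncoder, indent=1))


def read_particles(csv_path: PathLike, geometry_path: Optional[PathLike] = None) -> ParticleSet:
    """Read a particle CSV (columns id, x_nm, y_nm) plus optional geometry JSON.

    Malformed rows are rejected with their line numbers; particles outside
    the analyzed-region polygon are rejected with their ids.
    """
    df = pd.read_csv(csv_path)
    required = {"id", "x_nm", "y_nm"}
    if not required.issubset(df.columns):
        raise ValueError(f"{csv_path}: expected columns {sorted(required)}, found {list(df.columns)}")
    coords = df[["x_nm", "y_nm"]].apply(pd.to_numeric, errors="coerce")
    bad = coords.isna().any(axis=1)
    if bad.any():
        # +2: one for the header line, one for 1-based numbering
        lines = [int(i) + 2 for i in df.index[bad]]
        raise ValueError(f"{csv_path}: malformed coordinate rows at lines {lines}")

    region = None
    axis = None
    source = "frl"
    if geometry_path is not None:
        geom = json.loads(Path(geometry_path).read_text())
        region = Polygon(geom["analyzed_region_nm"])
        axis = CellAxis(
            direction=tuple(geom.get("axis_direction", (0.0, 1.0))),
            apical_edge_nm=float(geom["apical_edge_nm"]),
            basal_edge_nm=float(geom["basal_edge_nm"]),
        )
        source = geom.get("source", "frl")

    particles = ParticleSet(
        xy_nm=coords.to_numpy(dtype=float),
        ids=df["id"].to_numpy(),
        region=region,
        axis=axis,
        source=source,
    )
    if region is not None and len(particles):
        from shapely.geometry import Point

        eps = 1e-6 * max(1.0, region.length)
        outside = [
            particles.ids[i]
            for i, xy in enumerate(particles.xy_nm)
            if region.distance(Point(xy)) > eps
        ]
        if outside:
            raise ValueError(f"{csv_path}: particles outside the analyzed region: ids {list(outside)}")
    return particles
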