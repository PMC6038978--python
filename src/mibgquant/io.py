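"""File round-trips: NIfTI for image data, CSV/JSON for tables and models.

Volumes and projection stacks are stored as NIfTI (via nibabel); the
dynamic series is stored as a 3D NIfTI with time as the third axis.
Tabular outputs (TACs, polar maps, cohort manifests, reports) are plain
CSV/JSON so results diff cleanly under version control.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .phantom import ActivityVolume, DynamicSeries, PlanarImage, ProjectionSet

__all__ = [
    "save_nifti",
    "load_nifti",
    "save_dynamic_series",
    "load_dynamic_series",
    "save_planar_image",
    "load_planar_image",
    "save_projections",
    "load_projections",
    "save_volume",
    "load_volume",
    "save_json",
    "load_json",
    "tac_to_csv",
    "polar_map_to_csv",
    "config_hash",
]


def save_nifti(array: np.ndarray, path, spacing_mm: float = 1.0) -> None:
    affine = np.diag([spacing_mm] * 3 + [1.0])
    img = nib.Nifti1Image(np.asarray(array, dtype=np.float32), affine)
    nib.save(img, str(path))


def load_nifti(path) -> tuple[np.ndarray, float]:
    img = nib.load(str(path))
    spacing = float(img.header.get_zooms()[0])
    return np.asarray(img.get_fdata(), dtype=float), spacing


def save_dynamic_series(series: DynamicSeries, path) -> None:
    # (row, col, time): time as the third NIfTI axis
    save_nifti(np.moveaxis(series.frames, 0, -1), path, series.pixel_mm)


def load_dynamic_series(path, frame_duration_s: float = 1.0) -> DynamicSeries:
    data, spacing = load_nifti(path)
    return DynamicSeries(
        np.moveaxis(data, -1, 0), frame_duration_s=frame_duration_s, pixel_mm=spacing
    )


def save_planar_image(image: PlanarImage, path) -> None:
    save_nifti(image.counts[..., None], path, image.pixel_mm)


def load_planar_image(path, duration_s: float = 300.0) -> PlanarImage:
    data, spacing = load_nifti(path)
    return PlanarImage(np.squeeze(data, axis=-1), pixel_mm=spacing, duration_s=duration_s)


def save_projections(proj: ProjectionSet, path) -> None:
    save_nifti(np.moveaxis(proj.views, 0, -1), path, proj.voxel_mm)


def load_projections(path, view_duration_s: float = 20.0) -> ProjectionSet:
    data, spacing = load_nifti(path)
    views = np.moveaxis(data, -1, 0)
    angles = np.arange(views.shape[0]) * 360.0 / views.shape[0]
    return ProjectionSet(views, angles, view_duration_s=view_duration_s, voxel_mm=spacing)


def save_volume(volume: ActivityVolume, path) -> None:
    save_nifti(volume.concentration, path, volume.voxel_mm)


def load_volume(path) -> ActivityVolume:
    data, spacing = load_nifti(path)
    return ActivityVolume(data, voxel_mm=spacing)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def save_json(obj, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True) + "\n")


def load_json(path):
    return json.loads(Path(path).read_text())


def tac_to_csv(tac, path) -> None:
    pd.DataFrame({"t_s": tac.times, "counts": tac.counts}).to_csv(path, index=False)


def polar_map_to_csv(polar_map, path) -> None:
    rings, sectors = polar_map.values.shape
    rows = [
        {"ring": r, "sector": s, "value": polar_map.values[r, s]}
        for r in range(rings)
        for s in range(sectors)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    payload = json.dumps(_jsonable(obj), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
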