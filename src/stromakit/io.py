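"""File I/O: multi-page TIFF stacks with JSON sidecars, CSV tables.

Every image artifact on disk is a pair: ``<stem>.tif`` holding the pixel
data (multi-page for 3D) and ``<stem>.json`` holding the acquisition
geometry or phantom truth.  Tables are plain CSV with units in the column
headers.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import tifffile

from .fibers import FiberStack
from .oct import OCTVolume
from .saxs import DetectorGeometry, ScatterPattern

__all__ = [
    "write_stack",
    "read_stack",
    "write_sidecar",
    "read_sidecar",
    "write_oct_volume",
    "read_oct_volume",
    "write_scatter_pattern",
    "read_scatter_pattern",
    "write_fiber_stack",
    "read_fiber_stack",
]


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def write_stack(path: Path | str, data: np.ndarray) -> Path:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(data))
    return path


def read_stack(path: Path | str) -> np.ndarray:
    return tifffile.imread(Path(path))


def write_sidecar(path: Path | str, record: dict) -> Path:
    path = Path(path)
    path.write_text(json.dumps(_jsonable(record), indent=2) + "\n")
    return path


def read_sidecar(path: Path | str) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing sidecar {path}")
    return json.loads(path.read_text())


def _require(sidecar: dict, key: str, path: Path) -> object:
    if key not in sidecar:
        raise ValueError(f"sidecar {path} is missing required field {key!r}")
    return sidecar[key]


def write_oct_volume(stem: Path | str, volume: OCTVolume, extra: dict | None = None) -> Path:
    stem = Path(stem)
    write_stack(stem.with_suffix(".tif"), volume.intensity)
    record = {
        "kind": "oct_volume",
        "axial_scale_air_um_per_px": volume.axial_scale_air,
        "lateral_scale_um_per_px": volume.lateral_scale,
        "refractive_index": volume.refractive_index,
    }
    record.update(extra or {})
    write_sidecar(stem.with_suffix(".json"), record)
    return stem


def read_oct_volume(stem: Path | str) -> OCTVolume:
    stem = Path(stem)
    side_path = stem.with_suffix(".json")
    side = read_sidecar(side_path)
    return OCTVolume(
        intensity=read_stack(stem.with_suffix(".tif")).astype(float),
        axial_scale_air=float(_require(side, "axial_scale_air_um_per_px", side_path)),
        lateral_scale=float(_require(side, "lateral_scale_um_per_px", side_path)),
        refractive_index=float(side.get("refractive_index", 1.4)),
    )


def write_scatter_pattern(
    stem: Path | str, pattern: ScatterPattern, extra: dict | None = None
) -> Path:
    stem = Path(stem)
    write_stack(stem.with_suffix(".tif"), pattern.counts.astype(np.float32))
    geo = pattern.geometry
    record = {
        "kind": "scatter_pattern",
        "wavelength_nm": geo.wavelength_nm,
        "distance_mm": geo.distance_mm,
        "pixel_pitch_mm": geo.pixel_pitch_mm,
        "beam_center": list(geo.beam_center),
        "transect_position_mm": pattern.transect_position_mm,
    }
    record.update(extra or {})
    write_sidecar(stem.with_suffix(".json"), record)
    if pattern.mask is not None:
        write_stack(stem.parent / (stem.name + "_mask.tif"), pattern.mask.astype(np.uint8))
    return stem


def read_scatter_pattern(stem: Path | str) -> ScatterPattern:
    stem = Path(stem)
    side_path = stem.with_suffix(".json")
    side = read_sidecar(side_path)
    geo = DetectorGeometry(
        wavelength_nm=float(_require(side, "wavelength_nm", side_path)),
        distance_mm=float(_require(side, "distance_mm", side_path)),
        pixel_pitch_mm=float(_require(side, "pixel_pitch_mm", side_path)),
        beam_center=tuple(_require(side, "beam_center", side_path)),
    )
    mask_path = stem.parent / (stem.name + "_mask.tif")
    mask = read_stack(mask_path).astype(bool) if mask_path.exists() else None
    pos = side.get("transect_position_mm")
    return ScatterPattern(
        counts=read_stack(stem.with_suffix(".tif")).astype(float),
        geometry=geo,
        transect_position_mm=None if pos is None else float(pos),
        mask=mask,
    )


def write_fiber_stack(stem: Path | str, stack: FiberStack, extra: dict | None = None) -> Path:
    stem = Path(stem)
    data = stack.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    write_stack(stem.with_suffix(".tif"), data)
    record = {"kind": "fiber_stack", "voxel_size_nm": list(stack.voxel_size_nm)}
    record.update(extra or {})
    write_sidecar(stem.with_suffix(".json"), record)
    return stem


def read_fiber_stack(stem: Path | str) -> FiberStack:
    stem = Path(stem)
    side_path = stem.with_suffix(".json")
    side = read_sidecar(side_path)
    return FiberStack(
        data=read_stack(stem.with_suffix(".tif")),
        voxel_size_nm=tuple(float(v) for v in _require(side, "voxel_size_nm", side_path)),
    )
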