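"""Readers and writers shared by all pipelines.

Image data travel as multi-page TIFF with a YAML sidecar carrying the
physical metadata (exposure and frame rate for speckle stacks, voxel size
for confocal stacks) — units are never assumed. Tables are CSV, maps are
written both as 32-bit float TIFF and as NPY, and every run emits its fully
resolved configuration plus a manifest with SHA-256 checksums so outputs
are reproducible byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .flow import SpeckleStack
from .morphometry import ConfocalStack

__all__ = [
    "read_speckle_stack",
    "read_confocal_stack",
    "read_roi_mask",
    "write_image",
    "write_outputs",
]


def _load_yaml(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a YAML mapping")
    return data


def _require(meta: dict, key: str, path) -> float:
    if key not in meta:
        raise KeyError(f"{path}: missing required metadata field {key!r}")
    return meta[key]


def _read_pages(path) -> np.ndarray:
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    if not (np.issubdtype(arr.dtype, np.integer) or np.issubdtype(arr.dtype, np.floating)):
        raise ValueError(f"{path}: unsupported dtype {arr.dtype}")
    return arr


def read_speckle_stack(stack_path, meta_path) -> SpeckleStack:
    """Read a multi-page TIFF speckle stack with its YAML sidecar
    (required fields: ``exposure_T`` seconds, ``frame_rate`` Hz);
    page order is temporal order."""
    arr = _read_pages(stack_path)
    meta = _load_yaml(meta_path)
    return SpeckleStack(
        frames=arr,
        exposure_T=float(_require(meta, "exposure_T", meta_path)),
        frame_rate=float(_require(meta, "frame_rate", meta_path)),
        metadata={k: v for k, v in meta.items() if k not in ("exposure_T", "frame_rate")},
    )


def read_confocal_stack(stack_path, meta_path) -> ConfocalStack:
    """Read a multi-page TIFF z-stack with its YAML sidecar
    (required field: ``voxel_size_um`` as [z, y, x] in um)."""
    arr = _read_pages(stack_path)
    meta = _load_yaml(meta_path)
    voxel = _require(meta, "voxel_size_um", meta_path)
    voxel = tuple(float(v) for v in np.atleast_1d(voxel))
    if len(voxel) == 1:
        voxel = voxel * 3
    if len(voxel) != 3:
        raise ValueError(f"{meta_path}: voxel_size_um must have 1 or 3 entries")
    return ConfocalStack(
        volume=arr,
        voxel_size_um=voxel,
        metadata={k: v for k, v in meta.items() if k != "voxel_size_um"},
    )


def read_roi_mask(path) -> np.ndarray:
    """Read a binary ROI mask from PNG or TIFF (nonzero = inside)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        from PIL import Image

        arr = np.asarray(Image.open(path))
    if arr.ndim == 3:  # RGB(A) export of a mask
        arr = arr[..., :3].max(axis=-1)
    return arr > 0


def write_image(path, array: np.ndarray) -> None:
    """Write an image or stack as 32-bit float TIFF (pixel values preserved)."""
    tifffile.imwrite(path, np.asarray(array, dtype=np.float32), photometric="minisblack")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_outputs(
    out_dir,
    images: dict | None = None,
    tables: dict | None = None,
    config: dict | None = None,
) -> dict:
    """Write a run's outputs and return (and save) the manifest.

    ``images`` map name -> array (written as float32 TIFF and NPY),
    ``tables`` map name -> DataFrame (CSV), ``config`` is the fully
    resolved run configuration (YAML). The manifest lists every file with
    its SHA-256 checksum.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, arr in (images or {}).items():
        tif = out / f"{name}.tif"
        npy = out / f"{name}.npy"
        write_image(tif, arr)
        np.save(npy, np.asarray(arr))
        written += [tif, npy]
    for name, df in (tables or {}).items():
        csv = out / f"{name}.csv"
        pd.DataFrame(df).to_csv(csv, index=False)
        written.append(csv)
    if config is not None:
        cfg = out / "run_config.yaml"
        cfg.write_text(yaml.safe_dump(config, sort_keys=True))
        written.append(cfg)
    manifest = {p.name: _sha256(p) for p in written}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
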