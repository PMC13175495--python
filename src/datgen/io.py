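"""NIfTI-1 persistence for phantom studies and derived volumes.

Internal arrays are (z, y, x) with z index 0 the most superior slice; on
disk, volumes follow the NIfTI convention (x, y, z) with z increasing
superiorly, so the axial axis is transposed and flipped on the way through.
Early frames are written as one 4D file by default (five 3D files with
``split_frames``), the atlas as an integer volume, and study metadata
(class, severity, seed, ground-truth reduction factors) as a JSON sidecar.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import nibabel as nib
import numpy as np

from .phantom import DualPhaseStudy, RegionAtlas, StudyMeta


def _affine(voxel_mm: float) -> np.ndarray:
    return np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])


def _to_nifti_order(vol: np.ndarray) -> np.ndarray:
    # (z,y,x), z superior-first  ->  (x,y,z), z inferior-first
    return np.ascontiguousarray(vol.transpose(2, 1, 0)[:, :, ::-1])


def _from_nifti_order(arr: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(arr[:, :, ::-1].transpose(2, 1, 0))


def save_volume(vol: np.ndarray, voxel_mm: float, path: str | Path,
                dtype=np.float32):
    img = nib.Nifti1Image(_to_nifti_order(vol).astype(dtype), _affine(voxel_mm))
    img.header.set_zooms((voxel_mm,) * 3)
    nib.save(img, str(path))


def load_volume(path: str | Path) -> tuple[np.ndarray, float]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    return _from_nifti_order(data), float(img.header.get_zooms()[0])


def save_study(study: DualPhaseStudy, out_dir: str | Path,
               split_frames: bool = False):
    """Write one study: early (4D or five 3D), delayed, atlas, sidecar JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    voxel = study.atlas.voxel_mm
    if split_frames:
        for i, f in enumerate(study.early_frames):
            save_volume(f, voxel, out / f"early_frame{i}.nii.gz")
    else:
        stacked = np.stack([_to_nifti_order(f) for f in study.early_frames],
                           axis=-1).astype(np.float32)
        img = nib.Nifti1Image(stacked, _affine(voxel))
        nib.save(img, str(out / "early.nii.gz"))
    save_volume(study.delayed, voxel, out / "delayed.nii.gz")
    save_volume(study.atlas.labels, voxel, out / "atlas.nii.gz", dtype=np.int16)
    with open(out / "meta.json", "w") as fh:
        json.dump({"voxel_mm": voxel, "split_frames": split_frames,
                   **study.meta.to_dict()}, fh, indent=1)


def load_study(study_dir: str | Path) -> DualPhaseStudy:
    d = Path(study_dir)
    with open(d / "meta.json") as fh:
        meta = json.load(fh)
    voxel = float(meta.pop("voxel_mm"))
    split = meta.pop("split_frames", False)
    if split:
        frames = []
        i = 0
        while (d / f"early_frame{i}.nii.gz").exists():
            frames.append(load_volume(d / f"early_frame{i}.nii.gz")[0])
            i += 1
    else:
        img = nib.load(str(d / "early.nii.gz"))
        data = np.asarray(img.dataobj)
        frames = [_from_nifti_order(data[..., i]) for i in range(data.shape[-1])]
    if not frames:
        raise ValueError(f"{d}: no early frames found")
    delayed, _ = load_volume(d / "delayed.nii.gz")
    labels, _ = load_volume(d / "atlas.nii.gz")
    atlas = RegionAtlas(labels=labels.astype(np.int16), voxel_mm=voxel)
    reduction = meta.pop("reduction", {})
    sm = StudyMeta(**meta, reduction=reduction)
    return DualPhaseStudy(early_frames=[f.astype(np.float32) for f in frames],
                          delayed=delayed.astype(np.float32), atlas=atlas,
                          meta=sm)


def list_study_dirs(root: str | Path) -> list[Path]:
    root = Path(root)
    return sorted(p for p in root.iterdir()
                  if p.is_dir() and (p / "meta.json").exists())
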