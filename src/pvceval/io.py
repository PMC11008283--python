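"""File I/O: NIfTI volumes with JSON sidecars, deterministic CSV tables,
and run manifests with checksums."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from pvceval.phantom import ActivityVolume, LabelVolume, PhantomTruth

__all__ = [
    "file_sha256",
    "load_activity",
    "load_labels",
    "save_activity",
    "save_labels",
    "save_truth",
    "load_truth",
    "read_table",
    "write_json",
    "write_table",
]

SCAN_COLUMNS = [
    "subject_id", "study", "group", "tau_level",
    "visit_week", "time_years", "method", "roi", "suvr",
]


def _affine(voxel_size_mm: float) -> np.ndarray:
    aff = np.diag([voxel_size_mm] * 3 + [1.0])
    return aff


def save_activity(img: ActivityVolume, path) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(img.values.astype(np.float32), _affine(img.voxel_size_mm)), path)
    return path


def load_activity(path) -> ActivityVolume:
    nii = nib.load(str(path))
    voxel = float(nii.header.get_zooms()[0])
    return ActivityVolume(values=np.asarray(nii.dataobj, dtype=float), voxel_size_mm=voxel)


def save_labels(volume: LabelVolume, path) -> Path:
    """Writes the integer volume plus a ``<stem>.labels.json`` sidecar with
    the label map."""
    path = Path(path)
    nib.save(nib.Nifti1Image(volume.labels.astype(np.int16), _affine(volume.voxel_size_mm)), path)
    sidecar = path.with_name(path.name.split(".")[0] + ".labels.json")
    write_json({"label_map": volume.label_map, "voxel_size_mm": volume.voxel_size_mm}, sidecar)
    return path


def load_labels(path, sidecar=None) -> LabelVolume:
    path = Path(path)
    nii = nib.load(str(path))
    if sidecar is None:
        sidecar = path.with_name(path.name.split(".")[0] + ".labels.json")
    meta = json.loads(Path(sidecar).read_text())
    return LabelVolume(
        labels=np.asarray(nii.dataobj).astype(np.int32),
        voxel_size_mm=float(meta["voxel_size_mm"]),
        label_map={k: int(v) for k, v in meta["label_map"].items()},
    )


def save_truth(truth: PhantomTruth, path) -> Path:
    payload = {
        "true_activity": truth.true_activity,
        "atrophy_fraction": truth.atrophy_fraction,
        "label_map": truth.label_volume.label_map,
        "voxel_size_mm": truth.label_volume.voxel_size_mm,
    }
    return write_json(payload, path)


def load_truth(path) -> dict:
    return json.loads(Path(path).read_text())


def write_json(payload: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=_json_default) + "\n")
    return path


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, tuple)):
        return sorted(obj) if isinstance(obj, set) else list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_table(df: pd.DataFrame, path, columns=None) -> Path:
    """CSV with fixed column order and 9-significant-digit floats, so the
    file checksum is stable across platforms."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if columns is not None:
        df = df[[c for c in columns if c in df.columns]]
    df.to_csv(path, index=False, float_format="%.9g")
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def file_sha256(path) -> str:
    digest = hashlib.sha256()
    digest.update(Path(path).read_bytes())
    return digest.hexdigest()
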