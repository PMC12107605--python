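"""File formats: HDF5 recordings, NIfTI volumes, cohort CSV, provenance."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .forward import SensorArray
from .simulate import RawRecording
from .volume import VolumeGrid, VolumeMap

__all__ = ["write_recording", "read_recording", "write_map", "read_map",
           "write_mask", "read_mask", "write_cohort", "read_cohort",
           "provenance_record"]


def write_recording(rec: RawRecording, path: str | Path) -> Path:
    """One self-contained HDF5 file per subject: /meg, /eog, /fs, /sensors, /truth."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("meg", data=rec.data, compression="gzip", shuffle=True)
        f.create_dataset("eog", data=rec.eog)
        f["fs"] = rec.fs
        g = f.create_group("sensors")
        g["positions"] = rec.sensor_array.positions
        g["orientations"] = rec.sensor_array.orientations
        g.attrs["eog_channels"] = list(rec.sensor_array.eog_channels)
        f.attrs["subject_id"] = rec.subject_id
        t = f.create_group("truth")
        for key, val in rec.truth.items():
            t[key] = val
    return path


def read_recording(path: str | Path) -> RawRecording:
    with h5py.File(path, "r") as f:
        sensors = SensorArray(
            positions=f["sensors/positions"][()],
            orientations=f["sensors/orientations"][()],
            eog_channels=tuple(f["sensors"].attrs["eog_channels"]),
        )
        truth = {k: f["truth"][k][()] for k in f["truth"]}
        return RawRecording(
            data=f["meg"][()], fs=float(f["fs"][()]), eog=f["eog"][()],
            sensor_array=sensors, subject_id=str(f.attrs["subject_id"]),
            truth=truth,
        )


def write_map(vmap: VolumeMap, path: str | Path, fill: float = 0.0) -> Path:
    """Write a masked map as float32 NIfTI-1 on the RAS output grid."""
    path = Path(path)
    full = vmap.to_full(fill=fill).astype(np.float32)
    nib.save(nib.Nifti1Image(full, vmap.grid.affine), str(path))
    return path


def read_map(path: str | Path, mask: np.ndarray | None = None) -> VolumeMap:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    grid = VolumeGrid(affine=img.affine, shape=data.shape[:3])
    if mask is None:
        mask = np.ones(data.shape, bool)
    return VolumeMap(values=data[mask], grid=grid, mask=mask)


def write_mask(mask: np.ndarray, grid: VolumeGrid, path: str | Path) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), grid.affine), str(path))
    return path


def read_mask(path: str | Path) -> tuple[np.ndarray, VolumeGrid]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    return data > 0, VolumeGrid(affine=img.affine, shape=data.shape[:3])


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    cohort.to_csv(path, index=False)
    return path


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"subject_id", "happiness", "sex", "age", "iq"} - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    if df.isna().any().any():
        raise ValueError("cohort table contains missing values")
    if not df["happiness"].between(1, 7).all():
        raise ValueError("happiness scores must lie in [1, 7]")
    return df


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def provenance_record(config_dict: dict, seed: int, timings: dict | None = None,
                      inputs: list[str | Path] = ()) -> dict:
    """Provenance block written alongside every artifact."""
    from . import __version__
    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return {
        "config_hash": hashlib.sha256(blob).hexdigest(),
        "software_version": __version__,
        "seed": int(seed),
        "stage_timings_s": timings or {},
        "input_checksums": {str(p): _sha256(Path(p)) for p in inputs},
    }
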