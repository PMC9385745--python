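"""Reading and writing the pipeline's volume containers.

Raw 4D acquisitions and 3D angiograms travel as HDF5 (default) or as
multi-page TIFF stacks (one file per 3D block, repetitions suffixed
``_r<k>``); angiograms may also be written as NIfTI with the voxel pitch in
the affine.  Cohort manifests are CSV; cohort specs round-trip through YAML.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd
import tifffile
import yaml

from .svoct import AngioVolume
from .synthetic_data import CohortSpec, RawAcquisition


def write_acquisition_h5(raw: RawAcquisition, path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        d = f.create_dataset("intensity", data=raw.intensity, compression="gzip",
                             compression_opts=1)
        d.attrs["voxel_pitch_um"] = raw.voxel_pitch_um
        d.attrs["mouse_id"] = raw.mouse_id
        d.attrs["day"] = raw.day
        d.attrs["dose_class"] = raw.dose_class
    return path


def read_acquisition_h5(path) -> RawAcquisition:
    with h5py.File(path, "r") as f:
        d = f["intensity"]
        return RawAcquisition(
            intensity=d[...],
            voxel_pitch_um=tuple(d.attrs["voxel_pitch_um"]),
            mouse_id=str(d.attrs["mouse_id"]),
            day=int(d.attrs["day"]),
            dose_class=str(d.attrs["dose_class"]),
        )


def write_acquisition_tiff(raw: RawAcquisition, stem) -> list[Path]:
    """One multi-page TIFF per repetition: ``<stem>_r<k>.tif``, pages = Z."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    paths = []
    meta = {
        "voxel_pitch_um": list(raw.voxel_pitch_um),
        "mouse_id": raw.mouse_id,
        "day": raw.day,
        "dose_class": raw.dose_class,
    }
    for r in range(raw.intensity.shape[2]):
        p = stem.with_name(f"{stem.name}_r{r}.tif")
        # pages along depth: (Z, X, Y)
        tifffile.imwrite(p, np.moveaxis(raw.intensity[:, :, r, :], -1, 0),
                         photometric="minisblack", metadata=meta)
        paths.append(p)
    return paths


def read_acquisition_tiff(stem) -> RawAcquisition:
    stem = Path(stem)
    paths = sorted(stem.parent.glob(f"{stem.name}_r*.tif"))
    if not paths:
        raise FileNotFoundError(f"no repetition files matching {stem}_r*.tif")
    blocks = []
    meta = None
    for p in paths:
        with tifffile.TiffFile(p) as tf:
            blocks.append(np.moveaxis(tf.asarray(), 0, -1))
            if meta is None:
                meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    intensity = np.stack(blocks, axis=2)
    return RawAcquisition(
        intensity=intensity,
        voxel_pitch_um=tuple(meta.get("voxel_pitch_um", (1.0, 1.0, 1.0))),
        mouse_id=str(meta.get("mouse_id", "")),
        day=int(meta.get("day", 0)),
        dose_class=str(meta.get("dose_class", "")),
    )


def write_angio_tiff(vol: AngioVolume, path) -> Path:
    path = Path(path)
    tifffile.imwrite(
        path,
        np.moveaxis(vol.variance.astype(np.float32), -1, 0),
        photometric="minisblack",
        metadata={
            "voxel_pitch_um": list(vol.voxel_pitch_um),
            "mouse_id": vol.mouse_id,
            "day": vol.day,
            "dose_class": vol.dose_class,
        },
    )
    return path


def write_angio_nifti(vol: AngioVolume, path) -> Path:
    path = Path(path)
    affine = np.diag([*(p / 1000.0 for p in vol.voxel_pitch_um), 1.0])  # mm
    img = nib.Nifti1Image(vol.variance.astype(np.float32), affine)
    nib.save(img, path)
    return path


def read_angio_nifti(path) -> AngioVolume:
    img = nib.load(path)
    pitch = tuple(float(v) * 1000.0 for v in img.header.get_zooms()[:3])
    return AngioVolume(variance=np.asarray(img.dataobj), voxel_pitch_um=pitch)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"mouse_id", "dose_class", "day", "path"}
    if not required <= set(df.columns):
        raise ValueError(f"manifest missing columns {required - set(df.columns)}")
    return df


def spec_to_yaml(spec: CohortSpec, path) -> Path:
    path = Path(path)
    payload = asdict(spec)
    payload["raw_shape"] = list(spec.raw_shape)
    payload["days_by_mouse"] = {
        cls: {m: list(d) for m, d in mice.items()}
        for cls, mice in spec.days_by_mouse.items()
    }
    for key in ("root_radius", "step_length"):
        payload[key] = list(payload[key])
    with open(path, "w") as f:
        yaml.safe_dump(payload, f, sort_keys=False)
    return path


def spec_from_yaml(path) -> CohortSpec:
    with open(path) as f:
        payload = yaml.safe_load(f)
    payload["raw_shape"] = tuple(payload["raw_shape"])
    payload["days_by_mouse"] = {
        cls: {m: tuple(d) for m, d in mice.items()}
        for cls, mice in payload["days_by_mouse"].items()
    }
    for key in ("root_radius", "step_length"):
        if key in payload:
            payload[key] = tuple(payload[key])
    return CohortSpec(**payload)


def write_dataset_h5(tensor, path) -> Path:
    """Augmented dataset container: tensor + labels + provenance strings."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=tensor.samples, compression="gzip",
                         compression_opts=1)
        f.create_dataset("labels", data=tensor.labels)
        prov = [
            f"{p['mouse_id']}|{p['dose_class']}|{p['day']}|{p['augmentation']}"
            for p in tensor.provenance
        ]
        f.create_dataset("provenance", data=np.array(prov, dtype=object),
                         dtype=h5py.string_dtype())
    return path


def read_dataset_h5(path):
    from .dataset import InputTensor

    with h5py.File(path, "r") as f:
        samples = f["samples"][...]
        labels = f["labels"][...]
        provenance = []
        for s in f["provenance"][...]:
            mouse, cls, day, aug = s.decode().split("|")
            provenance.append(
                {"mouse_id": mouse, "dose_class": cls, "day": int(day),
                 "augmentation": aug}
            )
    return InputTensor(samples=samples, labels=labels, provenance=provenance)
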