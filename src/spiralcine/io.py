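"""HDF5 / NIfTI / PNG interchange for phantoms, k-space and reconstructions.

HDF5 layouts are ISMRMRD-style but written directly with h5py (complex
datasets plus per-acquisition attributes); ragged spiral frames are stored
one group per frame.
"""

from __future__ import annotations

import json
import os

import h5py
import nibabel as nib
import numpy as np

from spiralcine.gridding import GriddedKSpace, SamplingMask
from spiralcine.spiral import SpiralKSpace
from spiralcine.synthetic import CineImage, CoilMaps


def _ensure_dir(path: str) -> None:
    d = os.path.dirname(os.path.abspath(path))
    os.makedirs(d, exist_ok=True)


def save_cine_h5(
    path: str, cine: CineImage, maps: CoilMaps | None = None, config: dict | None = None
) -> None:
    _ensure_dir(path)
    with h5py.File(path, "w") as f:
        d = f.create_dataset("ground_truth", data=cine.data)
        d.attrs["frame_duration"] = cine.frame_duration
        d.attrs["norm_scale"] = cine.norm_scale
        d.attrs["is_normalized"] = cine.is_normalized
        if maps is not None:
            m = f.create_dataset("coil_maps", data=maps.data)
            m.attrs["calibration_origin"] = maps.calibration_origin
        if config is not None:
            f.attrs["config_json"] = json.dumps(config)


def load_cine_h5(path: str) -> tuple:
    with h5py.File(path, "r") as f:
        d = f["ground_truth"]
        cine = CineImage(
            d[...],
            frame_duration=float(d.attrs.get("frame_duration", 48e-3)),
            norm_scale=float(d.attrs.get("norm_scale", 1.0)),
            is_normalized=bool(d.attrs.get("is_normalized", False)),
        )
        maps = None
        if "coil_maps" in f:
            m = f["coil_maps"]
            maps = CoilMaps(
                m[...],
                calibration_origin=str(m.attrs.get("calibration_origin", "ground_truth")),
            )
        config = json.loads(f.attrs["config_json"]) if "config_json" in f.attrs else None
    return cine, maps, config


def save_spiral_h5(path: str, ksp: SpiralKSpace) -> None:
    _ensure_dir(path)
    with h5py.File(path, "w") as f:
        f.attrs["n_frames"] = ksp.n_frames
        f.attrs["samples_per_arm"] = ksp.samples_per_arm
        f.attrs["frame_duration"] = ksp.frame_duration
        if ksp.dc_signal is not None:
            f.create_dataset("dc_signal", data=ksp.dc_signal)
        for i in range(ksp.n_frames):
            g = f.create_group(f"frame_{i:04d}")
            g.create_dataset("data", data=ksp.samples[i])
            g.create_dataset("traj", data=ksp.coords[i])
            g.create_dataset("arm_ids", data=np.asarray(ksp.arm_ids[i]))
            g.attrs["frame_index"] = i


def load_spiral_h5(path: str) -> SpiralKSpace:
    with h5py.File(path, "r") as f:
        nf = int(f.attrs["n_frames"])
        samples, coords, arm_ids = [], [], []
        for i in range(nf):
            g = f[f"frame_{i:04d}"]
            samples.append(g["data"][...])
            coords.append(g["traj"][...])
            arm_ids.append(g["arm_ids"][...])
        dc = f["dc_signal"][...] if "dc_signal" in f else None
        return SpiralKSpace(
            samples=samples,
            coords=coords,
            arm_ids=arm_ids,
            samples_per_arm=int(f.attrs["samples_per_arm"]),
            dc_signal=dc,
            frame_duration=float(f.attrs["frame_duration"]),
        )


def save_gridded_h5(path: str, gridded: GriddedKSpace) -> None:
    _ensure_dir(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=gridded.data)
        f.create_dataset("mask", data=gridded.mask)
        if gridded.weight is not None:
            f.create_dataset("weight", data=gridded.weight)


def load_gridded_h5(path: str) -> GriddedKSpace:
    with h5py.File(path, "r") as f:
        return GriddedKSpace(
            data=f["data"][...],
            mask=f["mask"][...],
            weight=f["weight"][...] if "weight" in f else None,
        )


def cine_to_nifti(path: str, cine: CineImage) -> None:
    """Magnitude cine as a 3D NIfTI volume (x, y, time)."""
    _ensure_dir(path)
    mag = np.abs(cine.data).transpose(1, 2, 0)
    nib.save(nib.Nifti1Image(mag.astype(np.float32), np.eye(4)), path)


def mask_to_png(path: str, mask: SamplingMask | np.ndarray, frame: int = 0) -> None:
    from PIL import Image

    _ensure_dir(path)
    m = mask.mask if isinstance(mask, SamplingMask) else np.asarray(mask)
    if m.ndim == 3:
        m = m[frame]
    Image.fromarray((m * 255).astype(np.uint8)).save(path)


def save_provenance_json(path: str, provenance: dict) -> None:
    _ensure_dir(path)

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(provenance, fh, indent=2, default=default)
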