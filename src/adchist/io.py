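"""NIfTI reading and writing for b0/dw volume pairs."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .preprocess import VolumePair


def _affine(voxel_size: tuple[float, float, float]) -> np.ndarray:
    """RAS-oriented affine from voxel dimensions (mm)."""
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


def _load_array(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if np.isnan(data).any():
        raise ValueError(f"{path}: volume contains NaN voxels")
    return data


def read_volume_pair(
    b0_path: str | Path | None = None,
    dw_path: str | Path | None = None,
    four_d_path: str | Path | None = None,
    b_value: float = 1000.0,
) -> VolumePair:
    """Load a subject's pair from two 3-D files or one 4-D file.

    In the 4-D form, volume 0 is b0 and volume 1 is dw; extra trailing
    volumes are ignored.  Shapes must match and NaN voxels are rejected.
    """
    if four_d_path is not None:
        data = _load_array(four_d_path)
        if data.ndim != 4 or data.shape[3] < 2:
            raise ValueError(
                f"{four_d_path}: expected a 4-D volume with >= 2 frames"
            )
        b0, dw = data[..., 0], data[..., 1]
    else:
        if b0_path is None or dw_path is None:
            raise ValueError("provide b0_path and dw_path, or four_d_path")
        b0 = _load_array(b0_path)
        dw = _load_array(dw_path)
        if b0.shape != dw.shape:
            raise ValueError(
                f"shape mismatch: b0 {b0.shape} vs dw {dw.shape}"
            )
    return VolumePair(b0=b0, dw=dw, b_value=b_value)


def write_volume_pair(
    pair: VolumePair,
    b0_path: str | Path,
    dw_path: str | Path,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> None:
    """Write a pair as two float32 3-D NIfTI files."""
    aff = _affine(voxel_size)
    nib.save(nib.Nifti1Image(pair.b0.astype(np.float32), aff), str(b0_path))
    nib.save(nib.Nifti1Image(pair.dw.astype(np.float32), aff), str(dw_path))


def write_volume_pair_4d(
    pair: VolumePair,
    path: str | Path,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> None:
    """Write a pair as one float32 4-D NIfTI (frame 0 = b0, frame 1 = dw)."""
    stacked = np.stack([pair.b0, pair.dw], axis=-1).astype(np.float32)
    nib.save(nib.Nifti1Image(stacked, _affine(voxel_size)), str(path))
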