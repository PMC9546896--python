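"""Image-container helpers for voxelwise fitting.

Two containers are supported: NIfTI (the lingua franca for MRI parameter
maps; complex stacks travel as a real/imaginary volume pair) and HDF5
(which stores complex data natively). Parameter maps are written back in
the container the input arrived in.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .exceptions import ConfigError

__all__ = [
    "load_stack_nifti",
    "load_stack_h5",
    "load_mask",
    "write_maps_nifti",
    "write_maps_h5",
]


def load_stack_nifti(real_path, imag_path) -> tuple[np.ndarray, np.ndarray]:
    """Load a 4-D complex stack (one volume per TSL) from a real/imag NIfTI pair.

    Returns (data, affine); data is complex with shape (X, Y, Z, K).
    """
    real_img = nib.load(str(real_path))
    imag_img = nib.load(str(imag_path))
    real = np.asanyarray(real_img.dataobj, dtype=float)
    imag = np.asanyarray(imag_img.dataobj, dtype=float)
    if real.shape != imag.shape:
        raise ConfigError(f"real/imag shapes differ: {real.shape} vs {imag.shape}")
    if real.ndim != 4:
        raise ConfigError(f"expected a 4-D stack, got shape {real.shape}")
    return real + 1j * imag, real_img.affine


def load_stack_h5(path, dataset: str = "data") -> tuple[np.ndarray, None]:
    """Load a 4-D complex stack from HDF5 (complex dataset, or real/imag pair)."""
    with h5py.File(path, "r") as fh:
        if dataset in fh:
            data = fh[dataset][()]
            if not np.iscomplexobj(data):
                raise ConfigError(f"dataset {dataset!r} in {path} is not complex")
        elif "real" in fh and "imag" in fh:
            data = fh["real"][()] + 1j * fh["imag"][()]
        else:
            raise ConfigError(f"{path} must contain {dataset!r} or 'real'+'imag' datasets")
    if data.ndim != 4:
        raise ConfigError(f"expected a 4-D stack, got shape {data.shape}")
    return data, None


def load_mask(path) -> np.ndarray:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as fh:
            return np.asarray(fh["mask"][()], dtype=bool)
    return np.asanyarray(nib.load(str(path)).dataobj) > 0


def write_maps_nifti(maps: dict[str, np.ndarray], out_dir, affine) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, vol in maps.items():
        p = out_dir / f"{name}.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(vol, dtype=np.float64), affine), str(p))
        written.append(p)
    return written


def write_maps_h5(maps: dict[str, np.ndarray], out_path) -> Path:
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(out_path, "w") as fh:
        for name, vol in maps.items():
            fh.create_dataset(name, data=np.asarray(vol))
    return out_path
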