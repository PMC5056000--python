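"""Serialization helpers: NIfTI images, HDF5 filter banks, CSV tables."""

from __future__ import annotations

import csv
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .frames import FilterBank

__all__ = [
    "save_magnitude_phase_nifti",
    "load_nifti",
    "save_complex_array",
    "load_complex_array",
    "save_bank",
    "load_bank",
    "bank_to_csv",
    "write_metrics_csv",
]


def save_magnitude_phase_nifti(image: np.ndarray, stem: str | Path) -> tuple[Path, Path]:
    """Write a complex image as <stem>_magnitude.nii.gz and <stem>_phase.nii.gz."""
    stem = Path(stem)
    image = np.asarray(image, dtype=complex)
    paths = []
    for suffix, data in (("magnitude", np.abs(image)), ("phase", np.angle(image))):
        path = stem.parent / f"{stem.name}_{suffix}.nii.gz"
        nib.save(nib.Nifti1Image(data.astype(np.float64), affine=np.eye(4)), path)
        paths.append(path)
    return tuple(paths)


def load_nifti(path: str | Path) -> np.ndarray:
    """Read a NIfTI volume as a numpy array (squeezed)."""
    return np.squeeze(np.asarray(nib.load(str(path)).dataobj))


def save_complex_array(array: np.ndarray, path: str | Path) -> None:
    """Portable complex array as an .npz with real/imag planes."""
    array = np.asarray(array, dtype=complex)
    np.savez(path, real=array.real, imag=array.imag)


def load_complex_array(path: str | Path) -> np.ndarray:
    with np.load(path) as data:
        return data["real"] + 1j * data["imag"]


def save_bank(bank: FilterBank, path: str | Path) -> None:
    """Filter bank to HDF5 with layer/p/m metadata."""
    with h5py.File(path, "w") as h5:
        dset = h5.create_dataset("filters", data=bank.filters)
        dset.attrs["layer"] = bank.layer
        dset.attrs["p"] = bank.p
        dset.attrs["m"] = bank.m
        dset.attrs["uep_residual"] = bank.uep_residual


def load_bank(path: str | Path) -> FilterBank:
    with h5py.File(path, "r") as h5:
        dset = h5["filters"]
        return FilterBank(filters=dset[...], layer=str(dset.attrs["layer"]))


def bank_to_csv(bank: FilterBank, path: str | Path) -> None:
    """Human-readable dump of the m x p^2 filter matrix."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow([f"w{i}" for i in range(bank.p**2)])
        for row in bank.matrix:
            writer.writerow([repr(float(x)) for x in row])


def write_metrics_csv(rows: list[dict], path: str | Path) -> None:
    """Per-iteration metrics table: outer_iter, psnr_db, rel_err, ssim.

    Values are written with ``repr`` so identical runs produce
    bit-identical files.
    """
    columns = ["outer_iter", "psnr_db", "rel_err", "ssim"]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(columns)
        for row in rows:
            writer.writerow(
                [
                    repr(row[c]) if isinstance(row.get(c), float) else row.get(c, "")
                    for c in columns
                ]
            )
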