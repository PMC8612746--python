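"""File interfaces: NIfTI volumes, TSV tables, HDF5 Jacobian cache."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .phantom import HeadPhantom, MeasurementSet, OptodeArray
from .sensitivity import Jacobian


def save_nifti(volume: np.ndarray, voxel_size: float, path: str | Path) -> None:
    """Write a phantom-grid volume as NIfTI with an isotropic affine."""
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine)
    nib.save(img, str(path))


def save_phantom_nifti(phantom: HeadPhantom, path: str | Path) -> None:
    save_nifti(phantom.labels.astype(np.float32), phantom.voxel_size, path)


def optodes_to_tsv(array: OptodeArray, path: str | Path) -> None:
    rows = []
    for kind, positions in (
        ("source", array.source_positions),
        ("detector", array.detector_positions),
    ):
        for i, (x, y, z) in enumerate(positions):
            rows.append({"id": f"{kind[0]}{i}", "kind": kind,
                         "x_mm": x, "y_mm": y, "z_mm": z})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def channels_to_tsv(channels: MeasurementSet, path: str | Path) -> None:
    pd.DataFrame(
        {
            "src": channels.channels["src"],
            "det": channels.channels["det"],
            "sep_mm": channels.channels["sep_mm"],
            "nn": channels.channels["nn"],
        }
    ).to_csv(path, sep="\t", index=False)


def save_jacobian_h5(jac: Jacobian, path: str | Path) -> None:
    """Persist a Jacobian with its index maps (channel order preserved)."""
    with h5py.File(path, "w") as fh:
        fh.attrs["frequency_mhz"] = jac.frequency
        fh.attrs["wavelength_nm"] = jac.wavelength
        fh.create_dataset("intensity", data=jac.intensity, compression="gzip")
        if jac.phase is not None:
            fh.create_dataset("phase", data=jac.phase, compression="gzip")
        fh.create_dataset("voxel_indices", data=jac.voxel_indices)
        fh.create_dataset("channels", data=jac.channels)


def load_jacobian_h5(path: str | Path) -> Jacobian:
    with h5py.File(path, "r") as fh:
        return Jacobian(
            intensity=fh["intensity"][...],
            phase=fh["phase"][...] if "phase" in fh else None,
            frequency=float(fh.attrs["frequency_mhz"]),
            wavelength=int(fh.attrs["wavelength_nm"]),
            voxel_indices=fh["voxel_indices"][...],
            channels=fh["channels"][...],
        )


def write_manifest(path: str | Path, **entries) -> None:
    """JSON run manifest (config, seeds, versions)."""
    import fdhddot

    payload = {"fdhddot_version": fdhddot.__version__}
    payload.update(entries)

    def default(obj):
        if isinstance(obj, np.generic):
            return obj.item()
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return str(obj)

    Path(path).write_text(json.dumps(payload, indent=2, default=default))
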