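"""Reading and writing volumes (NIfTI-1), montages (JSON) and configs (YAML)."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .grid import GridSpec, LabelVolume

__all__ = [
    "write_label_volume", "read_label_volume",
    "write_field_volume", "read_field_volume",
    "write_json", "read_json",
]


def write_label_volume(vol: LabelVolume, path) -> None:
    """Save a label volume as integer NIfTI-1 plus a ``.planes.json`` sidecar."""
    path = Path(path)
    img = nib.Nifti1Image(vol.labels.astype(np.int16), vol.grid.affine())
    img.header.set_zooms((vol.grid.spacing,) * 3)
    nib.save(img, path)
    if vol.planes:
        sidecar = path.with_suffix("").with_suffix("")  # strip .nii / .nii.gz
        write_json(dict(vol.planes), str(sidecar) + ".planes.json")


def read_label_volume(path) -> LabelVolume:
    path = Path(path)
    img = nib.load(path)
    labels = np.asarray(img.dataobj).astype(np.int16)
    spacing = float(img.header.get_zooms()[0])
    origin = tuple(np.asarray(img.affine[:3, 3]) - 0.5 * spacing)
    grid = GridSpec(shape=labels.shape, spacing=spacing, origin=origin)
    sidecar = Path(str(path.with_suffix("").with_suffix("")) + ".planes.json")
    planes = read_json(sidecar) if sidecar.exists() else {}
    return LabelVolume(labels, grid, planes)


def write_field_volume(data: np.ndarray, grid: GridSpec, path) -> None:
    """Save a float field (potential, |E|, or an E component) as NIfTI-1."""
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), grid.affine())
    img.header.set_zooms((grid.spacing,) * data.ndim if data.ndim == 3
                         else (grid.spacing,) * 3 + (1.0,) * (data.ndim - 3))
    nib.save(img, path)


def read_field_volume(path) -> tuple[np.ndarray, GridSpec]:
    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=np.float64)
    spacing = float(img.header.get_zooms()[0])
    origin = tuple(np.asarray(img.affine[:3, 3]) - 0.5 * spacing)
    grid = GridSpec(shape=data.shape[:3], spacing=spacing, origin=origin)
    return data, grid


def write_json(obj, path) -> None:
    with open(path, "w") as f:
        json.dump(obj, f, indent=2, sort_keys=True)
        f.write("\n")


def read_json(path):
    with open(path) as f:
        return json.load(f)
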