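"""NIfTI and sidecar I/O.

Volumes travel as NIfTI with the voxel size in the affine; acquisition
facts that NIfTI cannot carry (PE axis, polarity, echo spacing, ...) go in
a JSON sidecar next to the image.
"""
from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .warp import EPIGeometry


def save_volume(path, data: np.ndarray, voxel_size, sidecar: dict | None = None):
    path = Path(path)
    voxel_size = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,))
    affine = np.diag(list(voxel_size) + [1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    img.header.set_zooms(tuple(voxel_size) + ((1.0,) if data.ndim == 4 else ()))
    nib.save(img, str(path))
    if sidecar is not None:
        sidecar_path(path).write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def sidecar_path(path) -> Path:
    path = Path(path)
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def load_volume(path):
    """Returns (data, voxel_size, sidecar-dict-or-None)."""
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    sc = sidecar_path(path)
    sidecar = json.loads(sc.read_text()) if sc.exists() else None
    return data, voxel_size, sidecar


def geometry_sidecar(geom: EPIGeometry) -> dict:
    return {
        "voxel_size_pe_mm": geom.voxel_size_pe,
        "n_pe": geom.n_pe,
        "echo_spacing_s": geom.echo_spacing_s,
        "accel": geom.accel,
        "pe_axis": geom.pe_axis,
        "pe_polarity": geom.pe_polarity,
    }


def geometry_from_sidecar(sidecar: dict) -> EPIGeometry:
    return EPIGeometry(
        voxel_size_pe=float(sidecar["voxel_size_pe_mm"]),
        n_pe=int(sidecar["n_pe"]),
        echo_spacing_s=float(sidecar["echo_spacing_s"]),
        accel=int(sidecar.get("accel", 1)),
        pe_axis=int(sidecar.get("pe_axis", 1)),
        pe_polarity=int(sidecar.get("pe_polarity", 1)),
    )
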