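"""Phantom/stack serialization: JSON specs, HDF5 realization stacks, NIfTI/PNG.

HDF5 stacks follow the fastMRI-style convention: a complex ``kspace``
dataset of shape (n_realizations, N, N), a float ``image`` dataset with
the magnitude reconstructions, and file attributes ``fov_mm``,
``sigma``, ``kind``, ``seed`` plus the full spec as JSON for lossless
round-tripping.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np

from .phantoms import (
    DiskSpec,
    KSpaceGrid,
    PhantomSpec,
    compound_kspace,
    realize,
)

__all__ = [
    "spec_to_dict",
    "spec_from_dict",
    "save_spec_json",
    "load_spec_json",
    "generate_stack",
    "save_stack",
    "load_stack",
    "export_nifti",
    "export_png",
]


def spec_to_dict(spec: PhantomSpec) -> dict:
    return {
        "kind": spec.kind,
        "fov_mm": spec.grid.fov_mm,
        "matrix_size": spec.grid.matrix_size,
        "noise_sigma": spec.noise_sigma,
        "seed": spec.seed,
        "disks": [dataclasses.asdict(d) for d in spec.disks],
        "layout": spec.layout,
    }


def spec_from_dict(data: dict) -> PhantomSpec:
    return PhantomSpec(
        kind=data["kind"],
        disks=tuple(DiskSpec(**d) for d in data["disks"]),
        grid=KSpaceGrid(data["fov_mm"], data["matrix_size"]),
        noise_sigma=data["noise_sigma"],
        seed=data["seed"],
        layout=data.get("layout", {}),
    )


def save_spec_json(spec: PhantomSpec, path: str | Path) -> None:
    Path(path).write_text(json.dumps(spec_to_dict(spec), indent=2))


def load_spec_json(path: str | Path) -> PhantomSpec:
    return spec_from_dict(json.loads(Path(path).read_text()))


def generate_stack(spec: PhantomSpec, n_realizations: int) -> tuple[np.ndarray, np.ndarray]:
    """All realizations of a phantom: (complex k-space, magnitude images)."""
    n = spec.grid.matrix_size
    kspace = np.empty((n_realizations, n, n), dtype=complex)
    images = np.empty((n_realizations, n, n), dtype=float)
    noiseless = compound_kspace(spec.grid, spec.disks)
    for k in range(n_realizations):
        ks, img = realize(spec, k, noiseless)
        kspace[k] = ks.values
        images[k] = img.magnitude
    return kspace, images


def save_stack(
    path: str | Path, spec: PhantomSpec, kspace: np.ndarray, images: np.ndarray
) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("kspace", data=kspace)
        f.create_dataset("image", data=images)
        f.attrs["fov_mm"] = spec.grid.fov_mm
        f.attrs["sigma"] = spec.noise_sigma
        f.attrs["kind"] = spec.kind
        f.attrs["seed"] = spec.seed
        f.attrs["layout"] = json.dumps(spec.layout)
        f.attrs["spec_json"] = json.dumps(spec_to_dict(spec))


def load_stack(path: str | Path) -> tuple[PhantomSpec, np.ndarray, np.ndarray]:
    with h5py.File(path, "r") as f:
        spec = spec_from_dict(json.loads(f.attrs["spec_json"]))
        return spec, f["kspace"][...], f["image"][...]


def export_nifti(magnitude: np.ndarray, pixel_mm: float, path: str | Path) -> None:
    """Write a magnitude image (or stack) as NIfTI with pixel spacing in the header."""
    import nibabel as nib

    data = np.asarray(magnitude, dtype=np.float32)
    if data.ndim == 2:
        data = data[..., None]
    elif data.ndim == 3:  # stack -> slices along the last axis
        data = np.moveaxis(data, 0, -1)
    affine = np.diag([pixel_mm, pixel_mm, 1.0, 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((pixel_mm, pixel_mm, 1.0))
    nib.save(img, str(path))


def export_png(magnitude: np.ndarray, path: str | Path) -> None:
    """Grayscale quick-look export."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plt.imsave(str(path), np.asarray(magnitude), cmap="gray")
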