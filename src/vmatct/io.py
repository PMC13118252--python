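"""Readers and writers for volumes and projection scenes.

Volumes: NIfTI (``.nii`` / ``.nii.gz``) via nibabel or MetaImage
(``.mha`` / ``.mhd``) via SimpleITK, with voxel size and origin carried in
the header.  Projection scenes: a single self-describing HDF5 container
(datasets ``/images``, ``/angles_deg``, ``/masks``) or a multi-page TIFF
with a JSON sidecar of angles.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import SimpleITK as sitk
import tifffile

from .geometry import DetectorMaskSet, ProjectionSet, Volume3D

__all__ = ["read_volume", "write_volume", "read_projections",
           "write_projections", "FormatError"]

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Raised when a file cannot be parsed as the expected format."""


def _is_nifti(path: Path) -> bool:
    return path.name.endswith((".nii", ".nii.gz"))


def _is_meta(path: Path) -> bool:
    return path.suffix in (".mha", ".mhd")


def write_volume(volume: Volume3D, path) -> None:
    path = Path(path)
    if _is_nifti(path):
        affine = np.diag([volume.voxel_size_mm] * 3 + [1.0])
        affine[:3, 3] = volume.origin_mm
        nib.save(nib.Nifti1Image(volume.values, affine), str(path))
    elif _is_meta(path):
        img = sitk.GetImageFromArray(np.ascontiguousarray(
            volume.values.transpose(2, 1, 0)))
        img.SetSpacing([volume.voxel_size_mm] * 3)
        img.SetOrigin(list(map(float, volume.origin_mm)))
        sitk.WriteImage(img, str(path))
    else:
        raise FormatError(f"unsupported volume format: {path.name}")


def read_volume(path) -> Volume3D:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if _is_nifti(path):
        img = nib.load(str(path))
        affine = img.affine
        voxel = float(affine[0, 0])
        scales = np.abs(np.diag(affine)[:3])
        if not np.allclose(scales, voxel):
            raise FormatError("only isotropic axis-aligned volumes supported")
        return Volume3D(np.asarray(img.dataobj, dtype=float), voxel,
                        affine[:3, 3].copy())
    if _is_meta(path):
        img = sitk.ReadImage(str(path))
        spacing = img.GetSpacing()
        if not np.allclose(spacing, spacing[0]):
            raise FormatError("only isotropic volumes supported")
        arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        return Volume3D(np.asarray(arr, dtype=float), float(spacing[0]),
                        np.asarray(img.GetOrigin(), dtype=float))
    raise FormatError(f"unsupported volume format: {path.name}")


def write_projections(projections: ProjectionSet, path) -> None:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("images", data=projections.images)
            f.create_dataset("angles_deg", data=projections.gantry_angles_deg)
            if projections.masks is not None:
                f.create_dataset("masks", data=projections.masks.masks)
    elif path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, projections.images.astype(np.float32))
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(
            {"angles_deg": projections.gantry_angles_deg.tolist()}))
    else:
        raise FormatError(f"unsupported projection format: {path.name}")


def read_projections(path) -> ProjectionSet:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            for name in ("images", "angles_deg"):
                if name not in f:
                    raise FormatError(f"missing dataset /{name} in {path.name}")
            images = f["images"][...]
            angles = f["angles_deg"][...]
            if "masks" in f:
                masks = DetectorMaskSet(f["masks"][...])
            else:
                logger.warning("%s has no /masks dataset; assuming all-true",
                               path.name)
                masks = DetectorMaskSet.all_true(images.shape[0],
                                                 images.shape[1:])
    elif path.suffix in (".tif", ".tiff"):
        images = np.asarray(tifffile.imread(path), dtype=float)
        if images.ndim == 2:
            images = images[None]
        sidecar = path.with_suffix(path.suffix + ".json")
        if not sidecar.exists():
            raise FormatError(f"missing angle sidecar {sidecar.name}")
        angles = np.asarray(json.loads(sidecar.read_text())["angles_deg"])
        logger.warning("TIFF scenes carry no masks; assuming all-true")
        masks = DetectorMaskSet.all_true(images.shape[0], images.shape[1:])
    else:
        raise FormatError(f"unsupported projection format: {path.name}")
    if images.shape[0] != np.atleast_1d(angles).shape[0]:
        raise FormatError("angle count does not match image count")
    return ProjectionSet(images, angles, masks)
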