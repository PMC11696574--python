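"""Reading and writing CT volumes and label maps.

NIfTI-1 (.nii/.nii.gz) is the primary format, handled by nibabel;
MetaImage (.mha/.mhd) is accepted via SimpleITK.  Arrays are kept in the
package's (z, y, x) axis convention with per-axis spacing taken from the
header — anisotropic spacing is preserved, never silently resampled.
Label files must hold integer-valued voxels (checked to 1e-6).
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .phantom import CTVolume, LabelMap

__all__ = ["read_volume", "read_labels", "write_volume", "write_labels", "resample_slices"]


def _read_array(path: Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        zooms = img.header.get_zooms()[:3]
        if any(z <= 0 for z in zooms):
            raise ValueError(f"{path}: missing or non-positive voxel spacing")
        data = np.asanyarray(img.dataobj)
        # nibabel loads (x, y, z); our convention is (z, y, x)
        return np.ascontiguousarray(data.T), (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    if suffixes.endswith((".mha", ".mhd")):
        img = sitk.ReadImage(str(path))
        sp = img.GetSpacing()  # (x, y, z)
        data = sitk.GetArrayFromImage(img)  # already (z, y, x)
        return np.asarray(data), (float(sp[2]), float(sp[1]), float(sp[0]))
    raise ValueError(f"unsupported image format: {path}")


def read_volume(path: str | Path, *, height_m: float | None = None, subject_id: str | None = None) -> CTVolume:
    """Load a CT volume in HU; spacing comes from the header per axis."""
    path = Path(path)
    data, spacing = _read_array(path)
    return CTVolume(
        data.astype(np.float64),
        spacing,
        height_m=height_m,
        subject_id=subject_id if subject_id is not None else path.name.split(".")[0],
    )


def read_labels(path: str | Path) -> LabelMap:
    """Load a label map; voxel values must be integers (to 1e-6)."""
    data, _spacing = _read_array(Path(path))
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if np.max(np.abs(data - rounded)) > 1e-6:
            bad = float(data.flat[int(np.argmax(np.abs(data - rounded)))])
            raise ValueError(f"label file contains non-integer value {bad}")
        data = rounded
    return LabelMap(data.astype(np.int32))


def _affine(spacing: tuple[float, float, float]) -> np.ndarray:
    # RAS-aligned diagonal affine from (z, y, x) spacing
    return np.diag([spacing[2], spacing[1], spacing[0], 1.0])


def write_volume(vol: CTVolume, path: str | Path) -> None:
    path = Path(path)
    if "".join(path.suffixes).endswith((".mha", ".mhd")):
        img = sitk.GetImageFromArray(vol.voxels.astype(np.float32))
        img.SetSpacing((vol.spacing_mm[2], vol.spacing_mm[1], vol.spacing_mm[0]))
        sitk.WriteImage(img, str(path))
        return
    nib.save(nib.Nifti1Image(vol.voxels.T.astype(np.float32), _affine(vol.spacing_mm)), str(path))


def write_labels(lab: LabelMap, path: str | Path, spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> None:
    path = Path(path)
    if "".join(path.suffixes).endswith((".mha", ".mhd")):
        img = sitk.GetImageFromArray(lab.labels.astype(np.int16))
        img.SetSpacing((spacing_mm[2], spacing_mm[1], spacing_mm[0]))
        sitk.WriteImage(img, str(path))
        return
    nib.save(nib.Nifti1Image(lab.labels.T.astype(np.int16), _affine(spacing_mm)), str(path))


def resample_slices(
    vol: CTVolume, target_interval_mm: float, labels: LabelMap | None = None
) -> CTVolume | tuple[CTVolume, LabelMap]:
    """Resample along the slice (z) axis to a target slice interval.

    Intensities are linearly interpolated, labels nearest-neighbour; the
    in-plane grid is untouched.  The first slice is kept fixed and the new
    grid covers the original z extent (edge replication at the boundary).
    """
    if target_interval_mm <= 0:
        raise ValueError("target interval must be > 0")
    nz = vol.voxels.shape[0]
    if nz < 2:
        raise ValueError("cannot resample a single-slice volume")
    dz = vol.spacing_mm[0]
    if np.isclose(dz, target_interval_mm):
        out_vol = CTVolume(vol.voxels.copy(), vol.spacing_mm, vol.height_m, vol.subject_id)
        return (out_vol, LabelMap(labels.labels.copy(), labels.side_codes, dict(labels.meta))) if labels else out_vol
    extent = (nz - 1) * dz
    n_new = int(np.floor(extent / target_interval_mm)) + 1
    zs = np.arange(n_new) * target_interval_mm / dz  # fractional source indices
    zs = np.clip(zs, 0, nz - 1)
    yy, xx = np.meshgrid(
        np.arange(vol.voxels.shape[1]), np.arange(vol.voxels.shape[2]), indexing="ij"
    )
    coords = [
        np.broadcast_to(zs[:, None, None], (n_new,) + yy.shape),
        np.broadcast_to(yy, (n_new,) + yy.shape),
        np.broadcast_to(xx, (n_new,) + xx.shape),
    ]
    new_spacing = (target_interval_mm, vol.spacing_mm[1], vol.spacing_mm[2])
    vox = ndimage.map_coordinates(vol.voxels, coords, order=1, mode="nearest")
    out_vol = CTVolume(vox, new_spacing, vol.height_m, vol.subject_id)
    if labels is None:
        return out_vol
    lab = ndimage.map_coordinates(labels.labels, coords, order=0, mode="nearest")
    return out_vol, LabelMap(lab.astype(labels.labels.dtype), labels.side_codes, dict(labels.meta))
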