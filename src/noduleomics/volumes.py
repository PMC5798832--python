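"""Image volumes, ROI patches and gray-level quantization.

The extractor operates on a 3D scalar volume (Hounsfield-unit-like
intensities) together with a co-registered binary mask delineating the
nodule. Everything downstream works on a :class:`RoiPatch`: the tight
bounding-box crop of the volume restricted to the mask. Voxels inside
the bounding box but outside the mask never contribute to a feature;
matrix features skip voxel pairs/runs that cross them and filter
features replace them by the nearest in-mask value before convolution.

Arrays are indexed ``(x, y, z)``, 0-based. Masks are binarized at 0.5
on load.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


class LoadError(RuntimeError):
    """A volume or mask file could not be read."""


class GeometryError(ValueError):
    """Array rank, shape or spacing violates the 3D-volume contract."""


class ParameterError(ValueError):
    """An operation parameter is out of its documented range."""


class EmptyRoiError(ValueError):
    """The mask contains no voxel."""


class DegenerateRoiError(ValueError):
    """The ROI is too small/uniform for the requested matrix statistic."""


@dataclass(frozen=True)
class ImageVolume:
    """A 3D scalar intensity grid with physical voxel spacing (mm)."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        vox = np.asarray(self.voxels, dtype=np.float64)
        if vox.ndim != 3:
            raise GeometryError(f"volume must be rank 3, got rank {vox.ndim}")
        if not np.all(np.isfinite(vox)):
            raise LoadError("volume contains non-finite intensities (NaN/Inf)")
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or not all(np.isfinite(s) and s > 0 for s in sp):
            raise GeometryError(f"spacing must be three positive finite lengths, got {self.spacing}")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing", sp)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass(frozen=True)
class RoiPatch:
    """Tight bounding-box crop of a volume plus its binary nodule mask."""

    voxels: np.ndarray
    mask: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        vox = np.asarray(self.voxels, dtype=np.float64)
        msk = np.asarray(self.mask, dtype=bool)
        if vox.ndim != 3 or msk.shape != vox.shape:
            raise GeometryError("patch mask must match voxel array shape (rank 3)")
        if not msk.any():
            raise EmptyRoiError("empty ROI")
        # tight crop: the mask touches every face of the patch
        for ax in range(3):
            first = msk.take(0, axis=ax)
            last = msk.take(-1, axis=ax)
            if not (first.any() and last.any()):
                raise GeometryError("patch is not a tight crop of its mask")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "mask", msk)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def values(self) -> np.ndarray:
        """In-mask intensities as a flat array."""
        return self.voxels[self.mask]


@dataclass(frozen=True)
class QuantizedPatch:
    """Gray-level codes of a patch; sentinel ``-1`` outside the mask."""

    levels: int
    codes: np.ndarray
    level_edges: np.ndarray
    spacing: tuple[float, float, float]

    @property
    def mask(self) -> np.ndarray:
        return self.codes >= 0

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def read_volume(path, fmt: str | None = None) -> ImageVolume:
    """Read a NIfTI (``.nii``/``.nii.gz``) or NRRD volume.

    Spacing is taken from the file header. Raises :class:`LoadError`
    for unreadable files and :class:`GeometryError` for non-3D data.
    """
    path = Path(path)
    if not path.exists():
        raise LoadError(f"cannot read volume: {path} does not exist")
    if fmt is None:
        name = path.name.lower()
        if name.endswith((".nii", ".nii.gz")):
            fmt = "nifti"
        elif name.endswith(".nrrd"):
            fmt = "nrrd"
        else:
            raise LoadError(f"cannot infer format of {path}; expected .nii/.nii.gz/.nrrd")
    if fmt == "nifti":
        import nibabel as nib

        try:
            img = nib.load(str(path))
            vox = np.asarray(img.get_fdata(), dtype=np.float64)
            zooms = img.header.get_zooms()[:3]
            origin = tuple(float(v) for v in img.affine[:3, 3])
        except Exception as exc:  # pragma: no cover - backend specific
            raise LoadError(f"failed to parse NIfTI file {path}: {exc}") from exc
    elif fmt == "nrrd":
        import SimpleITK as sitk

        try:
            img = sitk.ReadImage(str(path))
            # SimpleITK returns (z, y, x); our convention is (x, y, z)
            vox = sitk.GetArrayFromImage(img).transpose(2, 1, 0).astype(np.float64)
            zooms = img.GetSpacing()
            origin = tuple(float(v) for v in img.GetOrigin())
        except Exception as exc:  # pragma: no cover
            raise LoadError(f"failed to parse NRRD file {path}: {exc}") from exc
    else:
        raise ParameterError(f"unknown format {fmt!r}")
    if np.asarray(vox).ndim != 3:
        raise GeometryError(f"{path}: expected a 3D volume, got rank {np.asarray(vox).ndim}")
    if not np.all(np.isfinite(vox)):
        raise LoadError(f"{path}: volume contains non-finite voxels")
    return ImageVolume(vox, tuple(float(z) for z in zooms), origin)


def write_volume(volume: ImageVolume, path) -> None:
    """Write a volume as NIfTI with spacing encoded in the affine."""
    import nibabel as nib

    affine = np.diag(list(volume.spacing) + [1.0])
    affine[:3, 3] = volume.origin
    img = nib.Nifti1Image(volume.voxels, affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def load_mask(path) -> np.ndarray:
    """Read a mask volume and binarize at 0.5."""
    return read_volume(path).voxels > 0.5


def extract_roi(volume: ImageVolume, mask: np.ndarray) -> RoiPatch:
    """Crop the tight bounding box of ``mask`` out of ``volume``."""
    mask = np.asarray(mask)
    if mask.shape != volume.shape:
        raise GeometryError(
            f"mask shape {mask.shape} does not match volume shape {volume.shape}"
        )
    mask = mask.astype(bool)
    if not mask.any():
        raise EmptyRoiError("empty ROI")
    slices = []
    for ax in range(3):
        proj = mask.any(axis=tuple(a for a in range(3) if a != ax))
        idx = np.flatnonzero(proj)
        slices.append(slice(idx[0], idx[-1] + 1))
    sl = tuple(slices)
    return RoiPatch(volume.voxels[sl], mask[sl], volume.spacing)


def quantize_array(voxels: np.ndarray, mask: np.ndarray, levels: int) -> np.ndarray:
    """Equal-width binning of in-mask intensities into ``levels`` codes.

    Bins span the in-mask min–max range; a constant region maps wholly
    to code 0. Returns an int array with sentinel ``-1`` outside the mask.
    """
    if levels < 2:
        raise ParameterError(f"levels must be >= 2, got {levels}")
    vals = voxels[mask]
    vmin = vals.min()
    vmax = vals.max()
    codes = np.full(voxels.shape, -1, dtype=np.int32)
    if vmax == vmin:
        codes[mask] = 0
    else:
        width = (vmax - vmin) / levels
        c = np.floor((vals - vmin) / width).astype(np.int32)
        codes[mask] = np.clip(c, 0, levels - 1)
    return codes


def quantize(patch: RoiPatch, levels: int) -> QuantizedPatch:
    """Quantize a patch to ``levels`` equal-width gray levels."""
    codes = quantize_array(patch.voxels, patch.mask, levels)
    vals = patch.values()
    edges = np.linspace(vals.min(), vals.max(), levels + 1)
    return QuantizedPatch(levels=int(levels), codes=codes, level_edges=edges, spacing=patch.spacing)


def fill_out_of_mask(voxels: np.ndarray, mask: np.ndarray, spacing) -> np.ndarray:
    """Replace out-of-mask voxels by their nearest (physical distance)
    in-mask value, so convolutions never see background air."""
    from scipy.ndimage import distance_transform_edt

    if mask.all():
        return voxels.astype(np.float64, copy=True)
    ind = distance_transform_edt(~mask, sampling=spacing, return_indices=True)[1]
    return voxels[tuple(ind)].astype(np.float64)


def read_manifest(path) -> pd.DataFrame:
    """Read a cohort manifest CSV (case_id, image_path, mask_path, label).

    Relative paths are resolved against the manifest's directory.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = {"case_id", "image_path", "mask_path", "label"}
    missing = required - set(df.columns)
    if missing:
        raise LoadError(f"manifest {path} missing columns: {sorted(missing)}")
    if df.empty:
        raise LoadError(f"manifest {path} has no cases")
    if df["case_id"].duplicated().any():
        raise LoadError(f"manifest {path} has duplicate case_ids")
    base = path.parent
    for col in ("image_path", "mask_path"):
        df[col] = [str(p) if Path(p).is_absolute() else str(base / p) for p in df[col]]
    return df
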