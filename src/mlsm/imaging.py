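"""Volumetric plumbing: voxel grids, lesion masks, atlas parcellations.

All lesions and the atlas must live on one shared voxel grid; every
downstream step (smoothing, lesion-load extraction, weight back-projection)
assumes it. Volumes are read and written as NIfTI-1 via nibabel.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ContractError, VolumeFormatError

logger = logging.getLogger("mlsm")

#: Conversion factor between a Gaussian's full width at half maximum and
#: its standard deviation: FWHM = 2 * sqrt(2 ln 2) * sigma.
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

TISSUE_CLASSES = ("grey", "white", "commissural")


@dataclass(frozen=True)
class VoxelGrid:
    """Shared sampling grid: shape, voxel size and voxel-to-world affine."""

    dims: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float]
    affine: np.ndarray

    def __post_init__(self) -> None:
        if len(self.dims) != 3 or any(d < 1 for d in self.dims):
            raise VolumeFormatError(f"grid dims must be a positive integer triple, got {self.dims}")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise VolumeFormatError(f"voxel sizes must be positive, got {self.voxel_size_mm}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4) or abs(np.linalg.det(affine)) < 1e-12:
            raise VolumeFormatError("affine must be an invertible 4x4 matrix")
        object.__setattr__(self, "affine", affine)

    @classmethod
    def from_nifti(cls, img: nib.Nifti1Image) -> "VoxelGrid":
        zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(dims=tuple(int(d) for d in img.shape[:3]), voxel_size_mm=zooms,
                   affine=np.asarray(img.affine, dtype=float))

    @classmethod
    def isotropic(cls, dims: tuple[int, int, int], voxel_size_mm: float = 2.0) -> "VoxelGrid":
        """Axis-aligned grid with equal voxel size on every axis."""
        v = float(voxel_size_mm)
        affine = np.diag([v, v, v, 1.0])
        return cls(dims=tuple(int(d) for d in dims), voxel_size_mm=(v, v, v), affine=affine)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))


@dataclass
class LesionVolume:
    """One patient's lesion as values in [0,1] on a :class:`VoxelGrid`.

    Binary masks (manual delineations) have values in {0,1}; smoothing
    produces fractional values and clears ``is_binary``.
    """

    grid: VoxelGrid
    values: np.ndarray
    patient_id: str = ""
    is_binary: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != tuple(self.grid.dims):
            raise VolumeFormatError(
                f"values shape {self.values.shape} does not match grid dims {self.grid.dims}")
        vmin, vmax = float(self.values.min()), float(self.values.max())
        if vmin < 0.0 or vmax > 1.0:
            raise VolumeFormatError(f"lesion values must lie in [0,1], got [{vmin}, {vmax}]")
        if self.is_binary and not np.isin(self.values, (0.0, 1.0)).all():
            raise VolumeFormatError("binary lesion volume contains non-{0,1} values")

    @property
    def n_lesioned_voxels(self) -> int:
        if not self.is_binary:
            raise ContractError("voxel count is defined for binary masks only")
        return int(self.values.sum())


@dataclass
class AtlasDefinition:
    """Labeled parcellation volume plus its ROI lookup table.

    ``roi_table`` columns: label (positive int), name, tissue_class in
    {grey, white, commissural}. Its row order is fixed and defines the
    column order of every lesion load vector.
    """

    grid: VoxelGrid
    labels: np.ndarray
    roi_table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise VolumeFormatError("atlas labels must be integers")
        if self.labels.shape != tuple(self.grid.dims):
            raise VolumeFormatError("atlas label shape does not match grid dims")
        if self.labels.min() < 0:
            raise VolumeFormatError("atlas labels must be nonnegative (0 = background)")
        required = {"label", "name", "tissue_class"}
        if not required.issubset(self.roi_table.columns):
            raise VolumeFormatError(f"roi_table must have columns {sorted(required)}")
        tab = self.roi_table.reset_index(drop=True)
        if tab["label"].duplicated().any():
            raise VolumeFormatError("roi_table contains duplicate labels")
        bad = set(tab["tissue_class"]) - set(TISSUE_CLASSES)
        if bad:
            raise VolumeFormatError(f"unknown tissue classes {sorted(bad)}")
        present = np.unique(self.labels)
        present = present[present > 0]
        missing_from_table = set(present) - set(tab["label"])
        if missing_from_table:
            raise VolumeFormatError(
                f"voxel labels {sorted(missing_from_table)} absent from roi_table")
        empty = set(tab["label"]) - set(present)
        if empty:
            raise VolumeFormatError(f"ROIs {sorted(empty)} have no voxels")
        self.roi_table = tab

    @property
    def n_rois(self) -> int:
        return len(self.roi_table)

    @property
    def roi_labels(self) -> np.ndarray:
        """Labels in fixed roi_table order (defines LLV column order)."""
        return self.roi_table["label"].to_numpy()

    def voxel_counts(self) -> np.ndarray:
        """Voxel count per ROI, in roi_table order."""
        counts = np.bincount(self.labels.ravel(), minlength=int(self.labels.max()) + 1)
        return counts[self.roi_labels]


def load_volume(path: str | Path, expect_binary: bool = False,
                patient_id: str | None = None) -> LesionVolume:
    """Read a 3-D NIfTI volume as a lesion mask.

    With ``expect_binary`` the data are thresholded at 0.5 into {0,1}; a
    warning is logged if any voxel held a non-integral value.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
    except FileNotFoundError:
        raise
    except Exception as exc:  # nibabel raises a zoo of format errors
        raise VolumeFormatError(f"could not read {path}: {exc}") from exc
    data = np.squeeze(data)
    if data.ndim != 3:
        raise VolumeFormatError(f"{path}: expected a 3-D volume, got {data.ndim}-D data")
    grid = VoxelGrid.from_nifti(img)
    pid = patient_id if patient_id is not None else path.name.split(".")[0]
    if expect_binary:
        if not np.isin(data, (0.0, 1.0)).all():
            warnings.warn(f"{path}: non-binary values thresholded at 0.5", stacklevel=2)
            logger.warning("%s: non-binary values thresholded at 0.5", path)
        data = (data >= 0.5).astype(np.float64)
        return LesionVolume(grid=grid, values=data, patient_id=pid, is_binary=True)
    is_binary = bool(np.isin(data, (0.0, 1.0)).all())
    return LesionVolume(grid=grid, values=data, patient_id=pid, is_binary=is_binary)


def load_atlas(volume_path: str | Path, roi_table_path: str | Path) -> AtlasDefinition:
    """Read a labeled atlas volume plus its tab-separated ROI table."""
    volume_path = Path(volume_path)
    try:
        img = nib.load(str(volume_path))
        data = np.asarray(img.dataobj)
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise VolumeFormatError(f"could not read {volume_path}: {exc}") from exc
    data = np.squeeze(data)
    if data.ndim != 3:
        raise VolumeFormatError(f"{volume_path}: expected a 3-D volume, got {data.ndim}-D")
    labels = np.rint(np.asarray(data, dtype=np.float64)).astype(np.int32)
    roi_table = pd.read_csv(roi_table_path, sep="\t")
    return AtlasDefinition(grid=VoxelGrid.from_nifti(img), labels=labels, roi_table=roi_table)


def check_same_grid(a: LesionVolume | AtlasDefinition, b: LesionVolume | AtlasDefinition,
                    tol: float = 1e-3) -> bool:
    """True iff both volumes share dims, voxel size and affine within ``tol``."""
    ga, gb = a.grid, b.grid
    if tuple(ga.dims) != tuple(gb.dims):
        return False
    if not np.allclose(ga.voxel_size_mm, gb.voxel_size_mm, atol=tol, rtol=0):
        return False
    return bool(np.allclose(ga.affine, gb.affine, atol=tol, rtol=0))


def gaussian_smooth(mask: LesionVolume, fwhm_mm: float = 8.0) -> LesionVolume:
    """Smooth a lesion mask with a Gaussian kernel of the given FWHM.

    Per-axis sigma in voxels is ``fwhm_mm / (voxel_size_mm * 2*sqrt(2 ln 2))``.
    The volume edge is treated as non-brain (constant-zero padding), so
    lesions touching the edge lose mass. Output is clipped to [0,1].
    """
    if fwhm_mm <= 0:
        raise ContractError(f"fwhm_mm must be positive, got {fwhm_mm}")
    sigma_vox = [fwhm_mm * FWHM_TO_SIGMA / v for v in mask.grid.voxel_size_mm]
    smoothed = ndimage.gaussian_filter(mask.values, sigma=sigma_vox, mode="constant", cval=0.0)
    smoothed = np.clip(smoothed, 0.0, 1.0)
    return LesionVolume(grid=mask.grid, values=smoothed, patient_id=mask.patient_id,
                        is_binary=False)


def write_volume(volume: LesionVolume | AtlasDefinition, path: str | Path) -> Path:
    """Write a lesion (float32) or atlas (int32 labels) volume as NIfTI-1."""
    path = Path(path)
    if not path.parent.is_dir():
        raise IOError(f"directory {path.parent} does not exist")
    if isinstance(volume, AtlasDefinition):
        data = volume.labels.astype(np.int32)
    else:
        data = volume.values.astype(np.float32)
    img = nib.Nifti1Image(data, affine=volume.grid.affine)
    img.header.set_zooms(volume.grid.voxel_size_mm)
    nib.save(img, str(path))
    return path


def write_atlas(atlas: AtlasDefinition, volume_path: str | Path,
                roi_table_path: str | Path) -> None:
    """Write the atlas label volume plus its ROI table (TSV)."""
    write_volume(atlas, volume_path)
    atlas.roi_table.to_csv(roi_table_path, sep="\t", index=False)


def binarize(volume: LesionVolume, threshold: float = 0.5) -> LesionVolume:
    """Threshold a fractional volume back into a {0,1} mask."""
    return replace(volume, values=(volume.values >= threshold).astype(np.float64),
                   is_binary=True)
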