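"""NIfTI I/O and multi-contrast subject handling.

A subject is a pair of co-registered 3D volumes -- a FLAIR-like and an
MP2RAGE-UNI-like contrast -- plus, when available, a 3-class ground-truth
label volume (0 = background, 1 = white-matter lesion, 2 = cortical lesion).
Registration is assumed to have happened upstream; this module only checks
its postcondition (matching grids and voxel spacing).

The single in-scope preprocessing step lives here: z-score intensity
normalization over the whole volume.  No brain mask is used because the
pipeline performs no skull stripping, so whole-volume statistics are the
only mask-free choice.
"""

from __future__ import annotations

import dataclasses
import os
from typing import Optional

import nibabel as nib
import numpy as np

#: Recognised contrast tags.
CONTRASTS = ("FLAIR", "MP2RAGE")

#: Legal ground-truth label values.
BACKGROUND, WML, CL = 0, 1, 2
VALID_LABELS = frozenset({BACKGROUND, WML, CL})


class VolumeError(ValueError):
    """Raised on invalid volumes: bad dimensions, spacing, labels or intensities."""


@dataclasses.dataclass
class ImageVolume:
    """A 3D intensity volume with voxel spacing and a voxel-to-world affine.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar intensities in arbitrary units; must be finite.
    spacing : tuple of float
        Per-axis voxel size in millimetres; strictly positive.
    affine : ndarray, shape (4, 4)
        Voxel-index to world-coordinate map (NIfTI convention).
    contrast : str
        One of ``CONTRASTS``.
    """

    data: np.ndarray
    spacing: tuple
    affine: np.ndarray
    contrast: str

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise VolumeError(f"expected a 3D grid, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise VolumeError(f"spacing must be three positive values, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise VolumeError("volume contains non-finite intensities")
        if self.contrast not in CONTRASTS:
            raise VolumeError(f"unknown contrast {self.contrast!r}; expected one of {CONTRASTS}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise VolumeError("affine must be 4x4")

    @property
    def shape(self):
        return self.data.shape

    @property
    def voxel_volume_ul(self) -> float:
        """Volume of one voxel in microlitres (= mm^3)."""
        return float(np.prod(self.spacing))


@dataclasses.dataclass
class LabelVolume:
    """A 3-class lesion label grid: 0 background, 1 WML, 2 CL."""

    labels: np.ndarray
    spacing: tuple
    affine: Optional[np.ndarray] = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise VolumeError(f"expected a 3D label grid, got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            rounded = np.rint(self.labels)
            if not np.array_equal(rounded, self.labels):
                raise VolumeError("label grid contains non-integer values")
            self.labels = rounded.astype(np.uint8)
        extra = set(np.unique(self.labels)) - VALID_LABELS
        if extra:
            raise VolumeError(f"illegal label values {sorted(extra)}; allowed: {sorted(VALID_LABELS)}")
        self.labels = self.labels.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.affine is None:
            self.affine = np.diag(list(self.spacing) + [1.0])
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self):
        return self.labels.shape

    @property
    def voxel_volume_ul(self) -> float:
        return float(np.prod(self.spacing))


@dataclasses.dataclass
class SubjectCase:
    """Two co-registered contrast volumes plus an optional ground truth.

    ``flair`` and ``mp2rage`` must share grid dimensions and voxel spacing;
    a ``gt`` label volume, when present, must match them as well.  ``site``
    tags the acquisition centre and is used for stratified fold building.
    """

    subject_id: str
    flair: ImageVolume
    mp2rage: ImageVolume
    gt: Optional[LabelVolume] = None
    site: str = "site1"

    def __post_init__(self):
        if self.flair.shape != self.mp2rage.shape:
            raise VolumeError(
                f"channel dimension mismatch: FLAIR {self.flair.shape} vs MP2RAGE {self.mp2rage.shape}"
            )
        if not np.allclose(self.flair.spacing, self.mp2rage.spacing, rtol=1e-4):
            raise VolumeError(
                f"channel spacing mismatch: {self.flair.spacing} vs {self.mp2rage.spacing}"
            )
        if self.gt is not None:
            if self.gt.shape != self.flair.shape:
                raise VolumeError(
                    f"ground-truth dimension mismatch: {self.gt.shape} vs {self.flair.shape}"
                )

    @property
    def shape(self):
        return self.flair.shape

    @property
    def spacing(self):
        return self.flair.spacing


def _load_image(path, contrast: str) -> ImageVolume:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float32)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ImageVolume(data=data, spacing=spacing, affine=img.affine, contrast=contrast)


def load_case(flair_path, mp2rage_path, gt_path=None, subject_id: Optional[str] = None,
              site: str = "site1") -> SubjectCase:
    """Load a subject from NIfTI files, validating all case invariants.

    Raises :class:`VolumeError` on dimension/spacing mismatches, non-finite
    intensities or illegal ground-truth labels, and ``FileNotFoundError``
    for missing paths.
    """
    flair = _load_image(flair_path, "FLAIR")
    mp2rage = _load_image(mp2rage_path, "MP2RAGE")
    gt = None
    if gt_path is not None:
        if not os.path.exists(gt_path):
            raise FileNotFoundError(gt_path)
        img = nib.load(str(gt_path))
        labels = np.asanyarray(img.dataobj)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        gt = LabelVolume(labels=labels, spacing=spacing, affine=img.affine)
    if subject_id is None:
        base = os.path.basename(str(flair_path))
        subject_id = base.split(".")[0].replace("_flair", "")
    return SubjectCase(subject_id=subject_id, flair=flair, mp2rage=mp2rage, gt=gt, site=site)


def zscore_normalize(vol: ImageVolume) -> ImageVolume:
    """Return a copy with zero mean and unit (population) standard deviation.

    Statistics are taken over every voxel of the volume.  A zero-variance
    volume has no meaningful normalization and raises :class:`VolumeError`.
    Idempotent up to numerical tolerance.
    """
    if vol.data.size < 2:
        raise VolumeError("normalization needs at least 2 voxels")
    data = vol.data.astype(np.float64)
    mu = data.mean()
    sd = data.std()  # population (N) form
    if sd < 1e-12 * max(1.0, abs(mu)):
        raise VolumeError("zero-variance volume cannot be normalized")
    out = ((data - mu) / sd).astype(np.float32)
    return ImageVolume(data=out, spacing=vol.spacing, affine=vol.affine, contrast=vol.contrast)


def save_mask(mask: LabelVolume, reference: ImageVolume, path) -> None:
    """Write a label volume as uint8 NIfTI with the reference's affine/spacing."""
    if mask.shape != reference.shape:
        raise VolumeError(f"mask dims {mask.shape} do not match reference {reference.shape}")
    img = nib.Nifti1Image(mask.labels.astype(np.uint8), reference.affine)
    img.header.set_zooms(reference.spacing)
    nib.save(img, str(path))


def save_image(vol: ImageVolume, path) -> None:
    """Write an intensity volume as float32 NIfTI."""
    img = nib.Nifti1Image(vol.data.astype(np.float32), vol.affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))
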