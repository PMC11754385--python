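"""Template-space volume and label-map I/O, and the shared grid contract.

Every stage of the pipeline operates on volumes that already live on a common
template grid (e.g. MNI after spatial normalization, which is out of scope
here). This module defines the two in-memory containers — :class:`Volume` and
:class:`LabelAtlas` — reads and writes them as NIfTI-1, and provides the
grid-compatibility predicate that all downstream stages enforce instead of
resampling implicitly.

Conventions
-----------
* Voxel indices are 0-based; index ranges are half-open.
* World space follows RAS; loaders canonicalize axis order with nibabel's
  closest-canonical transform, so "left hemisphere" means negative world x.
* Left/right ROI membership always comes from atlas labels, never from
  coordinates (the phantom generator, which *places* the labels, is the one
  location allowed to use the x<0 rule).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

logger = logging.getLogger(__name__)

#: ROI names every atlas must resolve (striatum entries may be synthesized as
#: the union of the caudate and putamen labels of that hemisphere).
REQUIRED_ROIS = (
    "striatum_left",
    "striatum_right",
    "caudate_left",
    "caudate_right",
    "putamen_left",
    "putamen_right",
    "occipital",
)

GRID_SPACING_ATOL_MM = 1e-6


class VolumeLoadError(ValueError):
    """Raised when a file cannot be interpreted as a valid 3-D volume."""


@dataclass
class Volume:
    """A 3-D scalar field on a regular grid with a voxel-to-world affine.

    Parameters
    ----------
    data : ndarray
        3-D array of intensities (arbitrary units).
    affine : ndarray
        4x4 voxel-to-world map (mm).
    space : str
        Free-text tag of the coordinate space, e.g. ``"MNI"``.
    """

    data: np.ndarray
    affine: np.ndarray
    space: str = "MNI"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise VolumeLoadError(f"expected a 3-D volume, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise VolumeLoadError(f"degenerate shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise VolumeLoadError("affine must be 4x4")
        if not all(s > 0 for s in self.spacing):
            raise VolumeLoadError(f"non-positive voxel spacing {self.spacing}")

    @property
    def spacing(self) -> tuple[float, float, float]:
        """Per-axis voxel size in mm, derived from the affine column norms."""
        return tuple(float(np.linalg.norm(self.affine[:3, i])) for i in range(3))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "Volume":
        """Same grid, new intensities."""
        return Volume(data=np.asarray(data), affine=self.affine.copy(), space=self.space)


@dataclass
class LabelAtlas:
    """Integer label field sharing a Volume grid, with named ROIs.

    ``roi_map`` maps ROI names to integer label ids in ``labels``. A single
    integer field cannot represent the striatum and its caudate/putamen parts
    simultaneously, so ``striatum_left``/``striatum_right`` are resolved as
    the union of the corresponding caudate and putamen labels whenever they
    have no dedicated id.
    """

    labels: np.ndarray
    affine: np.ndarray
    roi_map: dict[str, int] = field(default_factory=dict)
    space: str = "MNI"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.labels.ndim != 3:
            raise VolumeLoadError("label field must be 3-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            # NIfTI round-trips may promote to float; accept exact integers.
            rounded = np.round(self.labels)
            if not np.array_equal(rounded, self.labels):
                raise VolumeLoadError("label field contains non-integer values")
            self.labels = rounded.astype(np.int32)
        for name in REQUIRED_ROIS:
            if self.mask(name).sum() == 0:
                raise VolumeLoadError(f"required ROI {name!r} is empty or unmapped")

    @property
    def spacing(self) -> tuple[float, float, float]:
        return tuple(float(np.linalg.norm(self.affine[:3, i])) for i in range(3))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def mask(self, name: str) -> np.ndarray:
        """Boolean voxel mask of a named ROI (striatum = caudate ∪ putamen)."""
        if name in self.roi_map:
            return self.labels == self.roi_map[name]
        if name in ("striatum_left", "striatum_right"):
            side = name.split("_")[1]
            return self.mask(f"caudate_{side}") | self.mask(f"putamen_{side}")
        raise KeyError(f"ROI {name!r} not in atlas (have {sorted(self.roi_map)})")


def read_volume(path: os.PathLike | str) -> Volume:
    """Load a NIfTI-1 file as a canonically oriented :class:`Volume`.

    Raises
    ------
    VolumeLoadError
        If the file is missing, not 3-D, or contains non-finite voxels
        (the error message names how many voxels are affected).
    """
    if not os.path.exists(path):
        raise VolumeLoadError(f"no such file: {path}")
    img = nib.as_closest_canonical(nib.load(str(path)))
    data = np.asarray(img.get_fdata(dtype=np.float32))
    if data.ndim != 3:
        raise VolumeLoadError(f"{path}: expected 3-D image, got ndim={data.ndim}")
    bad = int(np.count_nonzero(~np.isfinite(data)))
    if bad:
        raise VolumeLoadError(f"{path}: {bad} non-finite voxel(s); refusing to load")
    return Volume(data=data, affine=np.asarray(img.affine))


def write_volume(vol: Volume, path: os.PathLike | str) -> None:
    """Write a :class:`Volume` as NIfTI-1, preserving the affine bit-exactly."""
    if os.path.exists(path):
        logger.info("overwriting existing volume at %s", path)
    img = nib.Nifti1Image(vol.data.astype(np.float32), vol.affine)
    nib.save(img, str(path))


def read_atlas(path: os.PathLike | str, roi_map: dict[str, int]) -> LabelAtlas:
    """Load a NIfTI label map plus an ROI-name mapping."""
    if not os.path.exists(path):
        raise VolumeLoadError(f"no such file: {path}")
    img = nib.as_closest_canonical(nib.load(str(path)))
    labels = np.asarray(img.dataobj)
    return LabelAtlas(labels=labels, affine=np.asarray(img.affine), roi_map=dict(roi_map))


def write_atlas(atlas: LabelAtlas, path: os.PathLike | str) -> None:
    img = nib.Nifti1Image(atlas.labels.astype(np.int16), atlas.affine)
    nib.save(img, str(path))


def check_same_grid(a: Volume | LabelAtlas, b: Volume | LabelAtlas) -> bool:
    """True iff shapes are equal and spacings agree within 1e-6 mm."""
    return a.shape == b.shape and bool(
        np.allclose(a.spacing, b.spacing, atol=GRID_SPACING_ATOL_MM, rtol=0.0)
    )


def require_same_grid(a: Volume | LabelAtlas, b: Volume | LabelAtlas) -> None:
    """Hard-error form of :func:`check_same_grid` (no implicit resampling)."""
    if not check_same_grid(a, b):
        raise ValueError(
            f"grid mismatch: {a.shape}@{a.spacing} vs {b.shape}@{b.spacing}"
        )
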