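"""Preprocessing chain for DAT volumes.

The training-side chain is smooth → normalize → mask: modality-specific 3-D
Gaussian smoothing (10 mm FWHM for PET, 6 mm for SPECT), intensity
normalization by the maximum of the *training dataset* (frozen and reused at
test time), and brain masking. Generated (translated) images get a light
post-generation smooth (default 1.7 FWHM) to suppress grid-like texture.

Convolution uses reflect padding: it preserves interior sums and avoids edge
dimming of a masked brain. FWHM is interpreted in mm wherever a protocol
states mm; the post-generation filter width carries no unit in the protocol
it mirrors, so both interpretations are selectable (default mm).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume_io import LabelAtlas, Volume, require_same_grid

logger = logging.getLogger(__name__)

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

DEFAULT_PET_FWHM_MM = 10.0
DEFAULT_SPECT_FWHM_MM = 6.0
DEFAULT_POST_FWHM = 1.7
DEFAULT_POST_FWHM_UNITS = "mm"


@dataclass(frozen=True)
class NormalizationConstants:
    """Frozen intensity-normalization constant for one training dataset."""

    dataset_max: float
    provenance: str = ""

    def __post_init__(self) -> None:
        if not (self.dataset_max > 0):
            raise ValueError(f"dataset_max must be > 0, got {self.dataset_max}")


def gaussian_smooth(vol: Volume, fwhm_mm: float | tuple[float, float, float]) -> Volume:
    """Separable Gaussian convolution with per-axis sigma in voxels.

    sigma_axis = (fwhm_mm / spacing_axis) * 1/(2*sqrt(2*ln 2)).
    ``fwhm_mm = 0`` returns the input unchanged.
    """
    fwhm = np.broadcast_to(np.asarray(fwhm_mm, dtype=float), (3,))
    if np.any(fwhm < 0):
        raise ValueError(f"FWHM must be >= 0, got {fwhm_mm}")
    if np.all(fwhm == 0):
        return vol.with_data(vol.data.copy())
    sigma_vox = fwhm / np.asarray(vol.spacing) * FWHM_TO_SIGMA
    out = ndimage.gaussian_filter(vol.data.astype(np.float64), sigma=sigma_vox, mode="reflect")
    return vol.with_data(out)


def fit_normalization(dataset: list[Volume], provenance: str = "") -> NormalizationConstants:
    """Global maximum over all voxels of all training volumes.

    Raises on an empty dataset or a non-positive global maximum (an all-zero
    or negative-valued dataset cannot define a scale).
    """
    if not dataset:
        raise ValueError("cannot fit normalization on an empty dataset")
    global_max = float(max(np.max(v.data) for v in dataset))
    if global_max <= 0:
        raise ValueError(f"dataset maximum must be positive, got {global_max}")
    return NormalizationConstants(dataset_max=global_max, provenance=provenance)


def apply_normalization(vol: Volume, c: NormalizationConstants) -> Volume:
    """Divide every voxel by the frozen dataset maximum.

    Training-set maxima map to 1; test volumes may legitimately exceed 1.
    """
    return vol.with_data(vol.data / c.dataset_max)


def apply_brain_mask(vol: Volume, mask: Volume | LabelAtlas) -> Volume:
    """Zero all voxels outside the mask (binary Volume: data != 0; atlas: labels > 0)."""
    require_same_grid(vol, mask)
    if isinstance(mask, LabelAtlas):
        keep = mask.labels > 0
    else:
        keep = mask.data != 0
    return vol.with_data(np.where(keep, vol.data, 0.0))


def post_generation_smooth(
    vol: Volume, fwhm: float = DEFAULT_POST_FWHM, units: str = DEFAULT_POST_FWHM_UNITS
) -> Volume:
    """Light smoothing of generated images to remove grid-like texture.

    ``units="mm"`` delegates to :func:`gaussian_smooth`; ``units="voxels"``
    applies sigma = fwhm * 1/(2*sqrt(2*ln 2)) voxels on every axis regardless
    of spacing.
    """
    if fwhm < 0:
        raise ValueError(f"FWHM must be >= 0, got {fwhm}")
    if units == "mm":
        return gaussian_smooth(vol, fwhm)
    if units == "voxels":
        if fwhm == 0:
            return vol.with_data(vol.data.copy())
        sigma = fwhm * FWHM_TO_SIGMA
        out = ndimage.gaussian_filter(vol.data.astype(np.float64), sigma=sigma, mode="reflect")
        return vol.with_data(out)
    raise ValueError(f"units must be 'mm' or 'voxels', got {units!r}")


def preprocess_training_volume(
    vol: Volume, fwhm_mm: float, norm: NormalizationConstants, brain: Volume | LabelAtlas
) -> Volume:
    """Fixed training-side order: smooth → normalize → mask."""
    logger.debug("preprocess order: smooth(%s mm) -> normalize -> mask", fwhm_mm)
    return apply_brain_mask(apply_normalization(gaussian_smooth(vol, fwhm_mm), norm), brain)


def postprocess_generated_volume(
    vol: Volume,
    brain: Volume | LabelAtlas,
    fwhm: float = DEFAULT_POST_FWHM,
    units: str = DEFAULT_POST_FWHM_UNITS,
) -> Volume:
    """Fixed synthesis-side order: mask → post-generation smooth."""
    return post_generation_smooth(apply_brain_mask(vol, brain), fwhm, units)
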