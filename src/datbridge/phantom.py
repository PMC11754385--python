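"""Synthetic striatal DAT phantoms with ground-truth ROIs and binding ratios.

Real [11C]CFT-PET / [123I]FP-CIT-SPECT cohorts are not redistributable, so
every downstream stage (translation, quantification, FID, classification) is
exercised on phantoms that emulate the two cohorts' binding structure:

* a brain-shaped ellipsoidal background of unit mean intensity;
* six ellipsoidal ROIs — caudate and putamen, left/right, placed by the
  world x<0 = left rule (striatum = caudate ∪ putamen) — whose intensities
  are set so that the *noiseless* binding ratio against the occipital
  background region equals the spec'd target exactly;
* modality-specific Gaussian PSF blur applied before additive Gaussian noise
  (blur models scanner resolution, noise models counts — the standard
  emission-imaging ordering; additive rather than Poisson noise is a
  deliberate simplification);
* a left-minus-right additive binding offset modelling disease asymmetry.

Default population centers follow the published cohort statistics for
normal-control (NC) and Parkinson's disease (PD) groups in each modality
(striatal SBR near 2.05/1.10 for SPECT-like NC/PD, 1.57/0.92 for PET-like),
with the PD anterior–posterior gradient (putamen < caudate) enforced.
Region-level PET-like targets beyond the published caudate value are
emulation choices solved so the pooled striatal ratio hits the cohort center
under the fixed geometry below.

Ellipsoid geometry is a single constants table (fractions of grid shape) so
tests are stable; it is documented, not configurable per call. Centers use
``frac * (N-1)`` so left/right structures are exact mirror images on any
grid, making the discretized hemisphere voxel counts equal.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from . import preprocess
from .volume_io import LabelAtlas, Volume, write_atlas, write_volume

logger = logging.getLogger(__name__)

COHORTS = ("NC", "PD")
MODALITIES = ("PET_like", "SPECT_like")

#: Ellipsoid geometry as (center fractions, semi-axis fractions) of the grid.
#: Caudate is drawn with ~1.6x the putamen volume so that the pooled striatal
#: ratio lands on the published cohort centers given the per-region targets.
GEOMETRY: dict[str, tuple[tuple[float, float, float], tuple[float, float, float]]] = {
    "brain": ((0.50, 0.50, 0.50), (0.42, 0.45, 0.40)),
    "caudate_left": ((0.37, 0.60, 0.55), (0.050, 0.090, 0.100)),
    "caudate_right": ((0.63, 0.60, 0.55), (0.050, 0.090, 0.100)),
    "putamen_left": ((0.26, 0.48, 0.48), (0.050, 0.080, 0.070)),
    "putamen_right": ((0.74, 0.48, 0.48), (0.050, 0.080, 0.070)),
    "occipital": ((0.50, 0.16, 0.45), (0.140, 0.070, 0.100)),
}

LABEL_IDS = {
    "caudate_left": 1,
    "caudate_right": 2,
    "putamen_left": 3,
    "putamen_right": 4,
    "occipital": 5,
}

#: Per-region noiseless binding-ratio targets by (cohort, modality), chosen so
#: the pooled striatal SBR matches published cohort means (see module docs).
DEFAULT_TARGETS = {
    ("NC", "SPECT_like"): {"caudate": 2.02, "putamen": 2.10},
    ("PD", "SPECT_like"): {"caudate": 1.19, "putamen": 0.96},
    ("NC", "PET_like"): {"caudate": 1.17, "putamen": 2.21},
    ("PD", "PET_like"): {"caudate": 1.05, "putamen": 0.72},
}

#: Additive left-minus-right striatal binding offset (NC symmetric).
DEFAULT_ASYMMETRY = {
    ("NC", "SPECT_like"): 0.0,
    ("PD", "SPECT_like"): 0.19,
    ("NC", "PET_like"): 0.0,
    ("PD", "PET_like"): 0.15,
}

#: Cohort-level between-subject SD of the striatal target, from published
#: cohort spreads; used as the generate_cohort jitter SD.
COHORT_SBR_SD = {
    ("NC", "SPECT_like"): 0.42,
    ("PD", "SPECT_like"): 0.33,
    ("NC", "PET_like"): 0.20,
    ("PD", "PET_like"): 0.30,
}

#: Modality blur (scanner point-spread FWHM, mm) and relative noise SD.
#: SPECT-like volumes are blurrier and noisier than PET-like ones.
MODALITY_PSF_FWHM_MM = {"PET_like": 5.0, "SPECT_like": 9.0}
MODALITY_NOISE_SD = {"PET_like": 0.04, "SPECT_like": 0.06}

#: Jittered per-region targets are truncated below at this value.
MIN_TARGET_SBR = 0.1

DEFAULT_GRID_SHAPE = (32, 32, 32)
DEFAULT_SPACING_MM = (2.0, 2.0, 2.0)


@dataclass
class PhantomSpec:
    """Complete parameterization of one synthetic subject."""

    cohort: str
    modality: str
    grid_shape: tuple[int, int, int] = DEFAULT_GRID_SHAPE
    spacing_mm: tuple[float, float, float] = DEFAULT_SPACING_MM
    target_sbr: dict[str, float] = field(default_factory=dict)
    asymmetry: float = 0.0
    psf_fwhm_mm: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cohort not in COHORTS:
            raise ValueError(f"cohort must be one of {COHORTS}, got {self.cohort!r}")
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for name in ("caudate_left", "caudate_right", "putamen_left", "putamen_right"):
            if name not in self.target_sbr:
                raise ValueError(f"target_sbr missing region {name!r}")
        if self.cohort == "NC" and any(v <= 0 for v in self.target_sbr.values()):
            raise ValueError("NC target_sbr values must all be positive")
        if self.cohort == "PD":
            for side in ("left", "right"):
                if not self.target_sbr[f"putamen_{side}"] < self.target_sbr[f"caudate_{side}"]:
                    raise ValueError(
                        "PD phantoms require putamen target < caudate target "
                        "(anterior-posterior gradient)"
                    )


def default_spec(
    cohort: str,
    modality: str,
    grid_shape: tuple[int, int, int] = DEFAULT_GRID_SHAPE,
    spacing_mm: tuple[float, float, float] = DEFAULT_SPACING_MM,
    seed: int = 0,
) -> PhantomSpec:
    """Population-center spec for a cohort/modality pair.

    NC defaults are symmetric; PD defaults carry the asymmetry offset split
    evenly between hemispheres (left = target + a/2, right = target - a/2).
    """
    key = (cohort, modality)
    if key not in DEFAULT_TARGETS:
        raise ValueError(f"unknown cohort/modality pair {key}")
    base = DEFAULT_TARGETS[key]
    asym = DEFAULT_ASYMMETRY[key]
    targets = {}
    for region in ("caudate", "putamen"):
        targets[f"{region}_left"] = base[region] + asym / 2.0
        targets[f"{region}_right"] = base[region] - asym / 2.0
    return PhantomSpec(
        cohort=cohort,
        modality=modality,
        grid_shape=tuple(grid_shape),
        spacing_mm=tuple(spacing_mm),
        target_sbr=targets,
        asymmetry=asym,
        psf_fwhm_mm=MODALITY_PSF_FWHM_MM[modality],
        noise_sd=MODALITY_NOISE_SD[modality],
        seed=seed,
    )


def _ellipsoid_mask(shape: tuple[int, int, int], name: str) -> np.ndarray:
    center_f, semi_f = GEOMETRY[name]
    n = np.asarray(shape, dtype=float)
    center = center_f * (n - 1.0)
    semi = np.asarray(semi_f) * n
    if np.any(semi < 0.5):
        raise ValueError(f"grid {shape} too small to resolve ROI {name!r}")
    grids = np.indices(shape).astype(float)
    r2 = sum(((grids[i] - center[i]) / semi[i]) ** 2 for i in range(3))
    mask = r2 <= 1.0
    if not mask.any():
        raise ValueError(f"ROI {name!r} is empty on grid {shape}")
    return mask


def _phantom_affine(
    shape: tuple[int, int, int], spacing: tuple[float, float, float]
) -> np.ndarray:
    """RAS affine with the grid centered on the origin (low i = left, x<0)."""
    aff = np.eye(4)
    for i in range(3):
        aff[i, i] = spacing[i]
        aff[i, 3] = -spacing[i] * (shape[i] - 1) / 2.0
    return aff


def build_atlas(
    grid_shape: tuple[int, int, int] = DEFAULT_GRID_SHAPE,
    spacing_mm: tuple[float, float, float] = DEFAULT_SPACING_MM,
) -> LabelAtlas:
    """Ground-truth label map on a phantom grid (shared by all specs)."""
    labels = np.zeros(grid_shape, dtype=np.int32)
    # Later entries never overwrite earlier ones -> labels stay disjoint even
    # if two ellipsoids touch after discretization.
    for name, lid in LABEL_IDS.items():
        m = _ellipsoid_mask(grid_shape, name) & (labels == 0)
        if not m.any():
            raise ValueError(f"ROI {name!r} fully occluded on grid {grid_shape}")
        labels[m] = lid
    return LabelAtlas(
        labels=labels,
        affine=_phantom_affine(grid_shape, spacing_mm),
        roi_map=dict(LABEL_IDS),
        space="phantom",
    )


def brain_mask(
    grid_shape: tuple[int, int, int] = DEFAULT_GRID_SHAPE,
    spacing_mm: tuple[float, float, float] = DEFAULT_SPACING_MM,
) -> Volume:
    """Binary brain mask (the outer ellipsoid) as a Volume."""
    return Volume(
        data=_ellipsoid_mask(grid_shape, "brain").astype(np.float32),
        affine=_phantom_affine(grid_shape, spacing_mm),
        space="phantom",
    )


def generate_phantom(spec: PhantomSpec) -> tuple[Volume, LabelAtlas]:
    """Render one phantom: paint ROIs, blur with the PSF, add noise.

    Noiseless, blur-free phantoms reproduce the spec's per-region binding
    ratios exactly (the occipital background is held at intensity 1). Noise
    is additive Gaussian with SD = ``noise_sd`` x (mean brain intensity
    before noise), applied inside the brain only; negative results are
    clipped at 0 with a logged warning.
    """
    atlas = build_atlas(spec.grid_shape, spec.spacing_mm)
    brain = _ellipsoid_mask(spec.grid_shape, "brain")
    img = np.where(brain, 1.0, 0.0)
    for region in ("caudate_left", "caudate_right", "putamen_left", "putamen_right"):
        img[atlas.mask(region)] = 1.0 + spec.target_sbr[region]
    vol = Volume(
        data=img, affine=_phantom_affine(spec.grid_shape, spec.spacing_mm), space="phantom"
    )
    if spec.psf_fwhm_mm > 0:
        vol = preprocess.gaussian_smooth(vol, spec.psf_fwhm_mm)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        bg_mean = float(vol.data[brain].mean())
        noise = rng.normal(0.0, spec.noise_sd * bg_mean, size=vol.shape)
        data = vol.data + np.where(brain, noise, 0.0)
        n_clip = int(np.count_nonzero(data < 0))
        if n_clip:
            logger.warning("clipping %d negative voxel(s) to 0 after noise", n_clip)
            data = np.clip(data, 0.0, None)
        vol = vol.with_data(data)
    return vol, atlas


@dataclass
class PhantomSubject:
    """One simulated subject: rendered volume, labels, class, and provenance."""

    volume: Volume
    atlas: LabelAtlas
    cohort: str
    spec: PhantomSpec
    subject_id: str = ""


def generate_cohort(
    n_nc: int,
    n_pd: int,
    modality: str,
    seed: int,
    grid_shape: tuple[int, int, int] = DEFAULT_GRID_SHAPE,
    spacing_mm: tuple[float, float, float] = DEFAULT_SPACING_MM,
    jitter: bool = True,
) -> list[PhantomSubject]:
    """Simulate a cohort with between-subject variability.

    Per-subject targets are jittered around the cohort defaults with a common
    additive Gaussian offset (SD = published cohort spread, truncated so all
    targets stay >= 0.1, which also preserves the PD gradient); the asymmetry
    offset is jittered with half its default SD and truncated at 0.
    Deterministic given ``seed``.
    """
    if n_nc + n_pd < 1:
        raise ValueError("cohort must contain at least one subject")
    rng = np.random.default_rng(seed)
    subjects: list[PhantomSubject] = []
    plan = [("NC", i) for i in range(n_nc)] + [("PD", i) for i in range(n_pd)]
    for cohort, idx in plan:
        spec = default_spec(cohort, modality, grid_shape, spacing_mm)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        if jitter:
            shift = rng.normal(0.0, COHORT_SBR_SD[(cohort, modality)])
            targets = {
                k: max(v + shift, MIN_TARGET_SBR) for k, v in spec.target_sbr.items()
            }
            asym = max(0.0, rng.normal(spec.asymmetry, spec.asymmetry / 2.0 or 0.0))
            base = {r: (targets[f"{r}_left"] + targets[f"{r}_right"]) / 2.0
                    for r in ("caudate", "putamen")}
            targets = {}
            for region in ("caudate", "putamen"):
                targets[f"{region}_left"] = base[region] + asym / 2.0
                targets[f"{region}_right"] = max(base[region] - asym / 2.0, MIN_TARGET_SBR)
            spec = replace(spec, target_sbr=targets, asymmetry=asym, seed=sub_seed)
        else:
            spec = replace(spec, seed=sub_seed)
        vol, atlas = generate_phantom(spec)
        subjects.append(
            PhantomSubject(
                volume=vol,
                atlas=atlas,
                cohort=cohort,
                spec=spec,
                subject_id=f"{modality}_{cohort}_{idx:03d}",
            )
        )
    return subjects


def write_cohort(subjects: list[PhantomSubject], outdir: os.PathLike | str) -> str:
    """Write NIfTI volume + label map + JSON sidecar per subject, plus a manifest CSV.

    Returns the manifest path.
    """
    os.makedirs(outdir, exist_ok=True)
    rows = []
    for s in subjects:
        vpath = os.path.join(outdir, f"{s.subject_id}.nii.gz")
        apath = os.path.join(outdir, f"{s.subject_id}_labels.nii.gz")
        jpath = os.path.join(outdir, f"{s.subject_id}.json")
        write_volume(s.volume, vpath)
        write_atlas(s.atlas, apath)
        with open(jpath, "w") as fh:
            json.dump(asdict(s.spec), fh, indent=2, default=list)
        rows.append(
            {"subject_id": s.subject_id, "cohort": s.cohort,
             "volume": vpath, "labels": apath, "spec": jpath}
        )
    manifest = os.path.join(outdir, "manifest.csv")
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
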