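"""Semi-quantitative DAT measures: binding ratios, asymmetry, CNR.

The specific binding ratio of an ROI is

    (mean counts of ROI - mean counts of background) / mean counts of background,

with the background taken from a region within the occipital lobe. Striatal,
caudate and putamen ratios (SBR, CBR, PBR) pool the voxels of both
hemispheres; per-hemisphere ratios give the asymmetry |SBR_L - SBR_R|. The
contrast-to-noise ratio is

    CNR = (mean striatum - mean background) / SD of background counts.

Conventions fixed here: background SD uses the population (divide-by-N)
form; ROI membership is binary (label value defines membership, no
partial-volume weighting); the striatum is the union of caudate and putamen
labels when no dedicated striatum label exists. All measures are invariant
under global positive rescaling of intensities, so max-normalization never
changes them.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .volume_io import LabelAtlas, Volume, require_same_grid


@dataclass
class BindingReport:
    """Per-subject semi-quantitative summary."""

    subject_id: str
    cohort: str
    SBR: float
    CBR: float
    PBR: float
    SBR_L: float
    SBR_R: float
    asymmetry: float
    CNR: float


def binding_ratio(vol: Volume, roi: np.ndarray, background: np.ndarray) -> float:
    """(mean ROI - mean background) / mean background over boolean voxel sets."""
    roi = np.asarray(roi, dtype=bool)
    background = np.asarray(background, dtype=bool)
    if not roi.any():
        raise ValueError("ROI voxel set is empty")
    if not background.any():
        raise ValueError("background voxel set is empty")
    bg_mean = float(vol.data[background].mean())
    if bg_mean <= 0:
        raise ValueError(f"background mean must be positive, got {bg_mean}")
    return float((vol.data[roi].mean() - bg_mean) / bg_mean)


def cnr(vol: Volume, striatum: np.ndarray, background: np.ndarray) -> float:
    """(mean striatum - mean background) / population SD of background counts."""
    striatum = np.asarray(striatum, dtype=bool)
    background = np.asarray(background, dtype=bool)
    if not striatum.any() or not background.any():
        raise ValueError("striatum and background voxel sets must be nonempty")
    bg = vol.data[background]
    bg_sd = float(bg.std(ddof=0))
    if bg_sd <= 0:
        raise ValueError("background SD must be positive for CNR")
    return float((vol.data[striatum].mean() - bg.mean()) / bg_sd)


def report(
    vol: Volume,
    atlas: LabelAtlas,
    subject_id: str = "",
    cohort: str = "",
    hemisphere_mean: bool = False,
) -> BindingReport:
    """Full binding report for one volume against its label atlas.

    ``hemisphere_mean=True`` computes SBR/CBR/PBR as the mean of the two
    per-hemisphere ratios instead of pooling voxels (default: voxel pooling).
    """
    require_same_grid(vol, atlas)
    bg = atlas.mask("occipital")

    def ratio(*names: str) -> float:
        m = np.zeros(vol.shape, dtype=bool)
        for n in names:
            m |= atlas.mask(n)
        return binding_ratio(vol, m, bg)

    def bilateral(region: str) -> float:
        if hemisphere_mean:
            return 0.5 * (ratio(f"{region}_left") + ratio(f"{region}_right"))
        return ratio(f"{region}_left", f"{region}_right")

    sbr_l = ratio("striatum_left")
    sbr_r = ratio("striatum_right")
    striatum = atlas.mask("striatum_left") | atlas.mask("striatum_right")
    try:
        cnr_val = cnr(vol, striatum, bg)
    except ValueError:
        # degenerate noiseless background (possible only for synthetic data)
        cnr_val = float("nan")
    return BindingReport(
        subject_id=subject_id,
        cohort=cohort,
        SBR=bilateral("striatum"),
        CBR=bilateral("caudate"),
        PBR=bilateral("putamen"),
        SBR_L=sbr_l,
        SBR_R=sbr_r,
        asymmetry=abs(sbr_l - sbr_r),
        CNR=cnr_val,
    )


def reports_frame(reports: list[BindingReport]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in reports])


def cohort_table(reports: list[BindingReport]) -> pd.DataFrame:
    """Per-cohort mean ± SD summary (sample SD; a single report has SD 0)."""
    if not reports:
        raise ValueError("no reports to summarize")
    df = reports_frame(reports)
    metrics = ["SBR", "CBR", "PBR", "SBR_L", "SBR_R", "asymmetry", "CNR"]

    def sd(x: pd.Series) -> float:
        return 0.0 if len(x) < 2 else float(x.std(ddof=1))

    out = df.groupby("cohort")[metrics].agg(["mean", sd, "count"])
    out.columns = [f"{m}_{s if s != 'sd' else 'sd'}" for m, s in out.columns]
    return out.reset_index()
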