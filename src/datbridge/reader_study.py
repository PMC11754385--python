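"""Visual-grading analysis and reader diagnostic performance.

Blind visual assessment: each observer scores each image on four criteria
with a 3-point Likert scale (level of noise, presence of artifacts,
synthetic appearance, confidence in diagnosis) and gives a binary NC/PD
diagnosis. The visual grading analysis score for one criterion and one image
source is

    VGAS = sum over observers and images of S_c / (N_i * N_o),

i.e. the mean score, bounded in [1, 3]. Real-vs-synthetic VGAS distributions
are compared per criterion with the two-sided Mann-Whitney U test over
per-image mean scores (exact null distribution for group sizes <= 20,
normal approximation with tie correction above).

Reader diagnostic performance builds each reader's 2x2 confusion matrix per
image source; a binary reader's ROC has a single operating point, so their
AUC is the trapezoidal area (sensitivity + specificity)/2.

``compare_groups`` implements the test-selection policy used throughout:
Shapiro-Wilk normality at alpha = 0.05 gates Student's t (with 95% CI of the
mean difference) versus Mann-Whitney U; Cohen's d on the pooled SD is always
reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .classify import DiagnosticReport, confusion_metrics

CRITERIA = ("noise", "artifacts", "synthetic_appearance", "confidence")
SOURCES = ("real", "synthetic")
SHEET_COLUMNS = ("observer", "image", "source", *CRITERIA, "diagnosis")
VALID_SCORES = {1, 2, 3}
EXACT_U_MAX_N = 20


@dataclass
class ReaderSheet:
    """Per-observer, per-image Likert scores and diagnoses, plus ground truth.

    ``scores`` must contain the columns observer, image, source
    ('real'/'synthetic'), one integer 1-3 column per criterion, and a
    'diagnosis' column with 'NC'/'PD'. ``ground_truth`` maps image id ->
    'NC'/'PD'.
    """

    scores: pd.DataFrame
    ground_truth: dict[str, str]

    def __post_init__(self) -> None:
        df = self.scores
        missing = set(SHEET_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"reader sheet missing columns {sorted(missing)}")
        for c in CRITERIA:
            if not set(df[c].astype(int)) <= VALID_SCORES:
                raise ValueError(f"criterion {c!r} has scores outside {{1,2,3}}")
        if df.duplicated(subset=["observer", "image"]).any():
            raise ValueError("duplicate (observer, image) rows in reader sheet")
        bad_src = set(df["source"]) - set(SOURCES)
        if bad_src:
            raise ValueError(f"unknown image sources {bad_src}")

    @classmethod
    def from_csv(cls, path, ground_truth: dict[str, str] | None = None) -> "ReaderSheet":
        df = pd.read_csv(path)
        if ground_truth is None:
            if "truth" not in df.columns:
                raise ValueError("CSV has no 'truth' column and no ground truth given")
            ground_truth = dict(zip(df["image"], df["truth"]))
        return cls(scores=df, ground_truth=ground_truth)


def vgas(scores: np.ndarray | pd.DataFrame) -> float:
    """Sum of all scores divided by N_i * N_o for one criterion and source.

    Accepts the full N_i x N_o score grid (2-D array or pivoted frame);
    missing cells are an error — the grading design is a complete grid.
    """
    arr = np.asarray(scores, dtype=float)
    if np.any(~np.isfinite(arr)):
        raise ValueError("reader sheet has missing cells for this criterion")
    if not set(np.unique(arr).astype(int)) <= VALID_SCORES or np.any(arr != np.round(arr)):
        raise ValueError("scores must be integers in {1, 2, 3}")
    return float(arr.sum() / arr.size)


def _criterion_grid(sheet: ReaderSheet, criterion: str, source: str) -> pd.DataFrame:
    sub = sheet.scores[sheet.scores["source"] == source]
    if sub.empty:
        raise ValueError(f"no rows for source {source!r}")
    grid = sub.pivot(index="image", columns="observer", values=criterion)
    if grid.isna().any().any():
        raise ValueError(f"incomplete observer/image grid for criterion {criterion!r}")
    return grid


def mann_whitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided U test: exact null for small groups, else normal + tie correction."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    method = "exact" if max(len(x), len(y)) <= EXACT_U_MAX_N else "asymptotic"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns that exact p ignores ties
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def vgas_table(sheet: ReaderSheet) -> pd.DataFrame:
    """Per-criterion, per-source VGAS mean ± SD plus the real-vs-synthetic U test.

    The U test compares per-image mean scores (over observers) between the
    two sources, as the grading protocol's image-level comparison.
    """
    present = set(sheet.scores["source"])
    if len(present) < 2:
        raise ValueError("both image sources are required for the comparison")
    rows = []
    for criterion in CRITERIA:
        per_image = {}
        for source in SOURCES:
            grid = _criterion_grid(sheet, criterion, source)
            per_image[source] = grid.mean(axis=1).to_numpy()
            rows.append({
                "criterion": criterion, "source": source,
                "vgas": vgas(grid),
                "sd": float(np.asarray(grid, float).std(ddof=1)),
                "n_images": grid.shape[0], "n_observers": grid.shape[1],
            })
        u, p = mann_whitney(per_image["real"], per_image["synthetic"])
        for row in rows[-2:]:
            row["U"] = u
            row["p_real_vs_synthetic"] = p
    return pd.DataFrame(rows)


def reader_diagnostics(sheet: ReaderSheet) -> pd.DataFrame:
    """Per-reader, per-source confusion matrix, sens/spec/PPV/NPV and AUC.

    PD is the positive class. A binary reader's AUC equals
    (sensitivity + specificity)/2 — the trapezoidal area under their
    two-point ROC.
    """
    df = sheet.scores
    if df["diagnosis"].isna().any():
        raise ValueError("missing diagnoses in reader sheet")
    unknown = set(df["image"]) - set(sheet.ground_truth)
    if unknown:
        raise ValueError(f"no ground truth for images {sorted(unknown)[:5]}")
    rows = []
    for (observer, source), sub in df.groupby(["observer", "source"]):
        truth = sub["image"].map(sheet.ground_truth)
        pred = sub["diagnosis"]
        tp = int(((pred == "PD") & (truth == "PD")).sum())
        fp = int(((pred == "PD") & (truth == "NC")).sum())
        tn = int(((pred == "NC") & (truth == "NC")).sum())
        fn = int(((pred == "NC") & (truth == "PD")).sum())
        rep = confusion_metrics(tp, fp, tn, fn)
        rep.auc = (rep.sensitivity + rep.specificity) / 2.0
        rows.append({"observer": observer, "source": source,
                     "tp": tp, "fp": fp, "tn": tn, "fn": fn,
                     **rep.as_percent()})
    return pd.DataFrame(rows)


def reader_report(tp: int, fp: int, tn: int, fn: int) -> DiagnosticReport:
    """Confusion metrics plus the binary-reader AUC identity (sens+spec)/2."""
    rep = confusion_metrics(tp, fp, tn, fn)
    rep.auc = (rep.sensitivity + rep.specificity) / 2.0
    return rep


@dataclass
class GroupComparison:
    test_name: str
    statistic: float
    p_value: float
    ci95_mean_difference: tuple[float, float] | None
    cohen_d: float | None


def cohen_d(x: np.ndarray, y: np.ndarray) -> float | None:
    """(mean_x - mean_y) / pooled SD; None when the pooled SD is zero."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    pooled = np.sqrt(((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2))
    if pooled == 0:
        return None
    return float((x.mean() - y.mean()) / pooled)


def compare_groups(x: np.ndarray, y: np.ndarray, alpha: float = 0.05) -> GroupComparison:
    """Normality-gated two-sample comparison.

    Both samples pass Shapiro-Wilk at ``alpha`` -> two-sided Student's t with
    the 95% CI of the mean difference; otherwise two-sided Mann-Whitney U.
    Cohen's d is always reported (None for zero-variance degenerate samples).
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("need n >= 3 per sample for normality gating")
    d = cohen_d(x, y)
    degenerate = x.var() == 0 or y.var() == 0
    if not degenerate:
        normal = (stats.shapiro(x).pvalue > alpha) and (stats.shapiro(y).pvalue > alpha)
    else:
        normal = False
    if normal:
        tt = stats.ttest_ind(x, y)
        ci = tt.confidence_interval(0.95)
        return GroupComparison("student_t", float(tt.statistic), float(tt.pvalue),
                               (float(ci.low), float(ci.high)), d)
    u, p = mann_whitney(x, y)
    return GroupComparison("mann_whitney_u", u, p, None, d)
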