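"""Segmentation evaluation metrics and agreement/association statistics.

Metrics: Dice coefficient (DC), average symmetric surface distance (ASD,
mm), absolute volume error as a percentage of the ground-truth volume
(AVE) and absolute mean-HU error (AIE).  Statistics: Lin's concordance
correlation coefficient (CCC, population moments), Pearson correlation,
and the paired-comparison protocol: Shapiro normality check choosing
between Student's t-test and the Wilcoxon test, with Bonferroni
correction of the significance level across multiple comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

__all__ = [
    "EvalRecord",
    "AgreementStats",
    "TestResult",
    "dice",
    "asd",
    "boundary_voxels",
    "ave",
    "aie",
    "ccc",
    "agreement",
    "compare_groups",
]


@dataclass
class EvalRecord:
    """One structure instance's accuracy and uncertainty for one subject."""

    subject_id: str
    structure_id: int
    side: str
    dc: float
    asd_mm: float
    ave_pct: float
    aie_hu: float
    uncertainty: float


@dataclass
class AgreementStats:
    ccc: float
    pearson_rho: float
    n: int


@dataclass
class TestResult:
    test_name: str  # t_test | wilcoxon
    normality_p: tuple[float, ...]
    raw_p: float
    adjusted_alpha: float
    n_comparisons: int
    significant: bool
    paired: bool


def dice(gt_mask: np.ndarray, pred_mask: np.ndarray) -> float:
    """2|A∩B| / (|A|+|B|); both-empty is perfect vacuous agreement (1.0)."""
    if gt_mask.shape != pred_mask.shape:
        raise ValueError("mask shapes differ")
    a = np.asarray(gt_mask, dtype=bool)
    b = np.asarray(pred_mask, dtype=bool)
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        warnings.warn("Dice of two empty masks defined as 1.0", stacklevel=2)
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


_FACE_CONN = ndimage.generate_binary_structure(3, 1)


def boundary_voxels(mask: np.ndarray) -> np.ndarray:
    """Labeled voxels with at least one face-adjacent background neighbour."""
    m = np.asarray(mask, dtype=bool)
    interior = ndimage.binary_erosion(m, structure=_FACE_CONN, border_value=0)
    return m & ~interior


def asd(gt_mask: np.ndarray, pred_mask: np.ndarray, spacing_mm) -> float:
    """Average symmetric surface distance in mm.

    Mean, over boundary voxels of both masks, of the Euclidean distance to
    the nearest boundary voxel of the other mask (directed means averaged
    weighted by boundary size).  Physical distances honour anisotropic
    spacing via a spacing-weighted distance transform.
    """
    a = np.asarray(gt_mask, dtype=bool)
    b = np.asarray(pred_mask, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    if not a.any() or not b.any():
        raise ValueError("ASD undefined for an empty mask")
    sa, sb = boundary_voxels(a), boundary_voxels(b)
    dist_to_b = ndimage.distance_transform_edt(~sb, sampling=spacing_mm)
    dist_to_a = ndimage.distance_transform_edt(~sa, sampling=spacing_mm)
    total = dist_to_b[sa].sum() + dist_to_a[sb].sum()
    return float(total / (int(sa.sum()) + int(sb.sum())))


def ave(gt_volume_cc: float, pred_volume_cc: float) -> float:
    """Absolute volume error as % of the ground-truth volume."""
    if gt_volume_cc <= 0:
        raise ValueError("ground-truth volume must be > 0")
    return 100.0 * abs(pred_volume_cc - gt_volume_cc) / gt_volume_cc


def aie(gt_mean_hu: float, pred_mean_hu: float) -> float:
    """Absolute difference of the two mean HU values."""
    if not (np.isfinite(gt_mean_hu) and np.isfinite(pred_mean_hu)):
        raise ValueError("mean HU values must be finite")
    return abs(gt_mean_hu - pred_mean_hu)


def ccc(x, y) -> float:
    """Lin's concordance correlation coefficient with population moments:
    2 cov(x,y) / (var(x) + var(y) + (mean(x) - mean(y))^2)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be equal-length 1D vectors of size >= 2")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()  # population (1/n)
    cov = ((x - mx) * (y - my)).mean()
    denom = vx + vy + (mx - my) ** 2
    if denom == 0:
        raise ValueError("CCC undefined: zero variance with equal means")
    return float(2.0 * cov / denom)


def agreement(x, y) -> AgreementStats:
    """CCC plus Pearson correlation for a pair of measurement vectors."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    rho = float(stats.pearsonr(x, y).statistic)
    return AgreementStats(ccc=ccc(x, y), pearson_rho=rho, n=x.size)


def compare_groups(a, b, *, paired: bool = True, n_comparisons: int = 1, alpha: float = 0.05) -> TestResult:
    """Shapiro-gated t-test/Wilcoxon with Bonferroni-adjusted significance.

    Normality (Shapiro, p > 0.05 required of every group, and of the
    differences when paired) selects Student's t-test; otherwise the
    Wilcoxon signed-rank test (paired) or rank-sum test (unpaired, labeled
    distinctly).  The per-comparison level is alpha / n_comparisons, e.g.
    0.05/3 ~ 0.0167.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs >= 3 values")
    if paired and a.size != b.size:
        raise ValueError("paired comparison requires equal sizes")
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")

    groups = [a, b] + ([a - b] if paired else [])
    norm_ps = []
    normal = True
    for g in groups:
        if np.ptp(g) == 0:  # Shapiro undefined on constant data
            warnings.warn("constant data: Shapiro undefined, falling back to Wilcoxon", stacklevel=2)
            norm_ps.append(float("nan"))
            normal = False
            continue
        p = float(stats.shapiro(g).pvalue)
        norm_ps.append(p)
        normal = normal and p > 0.05

    adjusted_alpha = alpha / n_comparisons
    if normal:
        test_name = "t_test"
        res = stats.ttest_rel(a, b) if paired else stats.ttest_ind(a, b)
        raw_p = float(res.pvalue)
    elif paired:
        test_name = "wilcoxon"
        d = a - b
        if np.all(d == 0):
            raw_p = 1.0
        else:
            raw_p = float(stats.wilcoxon(a, b).pvalue)
    else:
        test_name = "wilcoxon_rank_sum"
        raw_p = float(stats.ranksums(a, b).pvalue)
    return TestResult(
        test_name=test_name,
        normality_p=tuple(norm_ps),
        raw_p=raw_p,
        adjusted_alpha=adjusted_alpha,
        n_comparisons=n_comparisons,
        significant=bool(raw_p < adjusted_alpha),
        paired=paired,
    )
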