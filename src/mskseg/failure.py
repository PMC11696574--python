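"""Uncertainty-based segmentation failure detection.

On an annotated cohort the Dice distribution of each structure defines
robust outlier thresholds Median_DC + 1.4826 * k * MAD_DC with k = -2
("inaccurate", correctable with moderate effort) and k = -3 ("failed").
The structure-wise predictive uncertainty is scored as a detector of
below-threshold cases via AUROC (exact rank statistic, ties at 0.5), and
an ordinary least-squares line DC = a + b * u inverted at the DC
thresholds yields uncertainty cut-offs that can screen *unannotated*
volumes: cases whose uncertainty exceeds u* = (DC* - a)/b are flagged.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "MAD_SCALE",
    "FailureModel",
    "mad_threshold",
    "detect_auroc",
    "fit_dc_uncertainty_regression",
    "uncertainty_threshold_from_regression",
    "fit_failure_model",
    "screen_unlabeled",
]

MAD_SCALE = 1.4826  # rescales MAD to an SD-equivalent under normality
K_INACCURATE = -2.0
K_FAILED = -3.0


@dataclass
class FailureModel:
    """Per-structure (or all-structure-average) failure-detection model."""

    structure_id: int | str  # int or "all_structures_average"
    dc_median: float
    dc_mad: float
    dc_threshold_k2: float
    dc_threshold_k3: float
    regression_intercept: float  # a in DC = a + b*u
    regression_slope: float  # b (expected < 0)
    pearson_rho: float
    uncertainty_threshold_k2: float
    uncertainty_threshold_k3: float
    auroc_k2: float | None
    auroc_k3: float | None
    n: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "FailureModel":
        return cls(**json.loads(Path(path).read_text()))


def mad_threshold(dcs: Sequence[float], k: float) -> float:
    """median(dcs) + 1.4826 * k * median(|dcs - median(dcs)|)."""
    dcs = np.asarray(dcs, dtype=np.float64)
    if dcs.size < 3:
        raise ValueError("need at least 3 Dice values")
    if np.any((dcs < 0) | (dcs > 1)):
        raise ValueError("Dice values must lie in [0,1]")
    med = float(np.median(dcs))
    mad = float(np.median(np.abs(dcs - med)))
    return med + MAD_SCALE * k * mad


def detect_auroc(uncertainties: Sequence[float], dcs: Sequence[float], dc_threshold: float) -> float | None:
    """AUROC of uncertainty for detecting dc < dc_threshold cases.

    Computed as the normalized Mann-Whitney U statistic (ties count 0.5),
    i.e. exactly the probability that a random positive's uncertainty
    ranks above a random negative's.  Returns None (undefined) when one of
    the classes is absent — the printed tables use "–" for such cells.
    """
    u = np.asarray(uncertainties, dtype=np.float64)
    d = np.asarray(dcs, dtype=np.float64)
    keep = np.isfinite(u)
    u, d = u[keep], d[keep]
    pos = d < dc_threshold
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = stats.rankdata(u)  # average ranks handle ties -> 0.5 credit
    u_stat = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u_stat / (n_pos * n_neg))


def fit_dc_uncertainty_regression(uncertainties: Sequence[float], dcs: Sequence[float]) -> dict:
    """OLS of DC (dependent) on predictive uncertainty (independent).

    Returns {"a": intercept, "b": slope, "pearson_rho": rho, "n": n}.
    """
    u = np.asarray(uncertainties, dtype=np.float64)
    d = np.asarray(dcs, dtype=np.float64)
    keep = np.isfinite(u) & np.isfinite(d)
    u, d = u[keep], d[keep]
    if u.size < 3:
        raise ValueError("need at least 3 records")
    if np.ptp(u) == 0:
        raise ValueError("uncertainty is constant; regression undefined")
    res = stats.linregress(u, d)
    return {"a": float(res.intercept), "b": float(res.slope), "pearson_rho": float(res.rvalue), "n": int(u.size)}


def uncertainty_threshold_from_regression(reg: Mapping[str, float], dc_threshold: float) -> float:
    """Invert DC = a + b*u at a DC threshold: u* = (DC* - a) / b.

    Requires b < 0 (uncertainty anti-correlates with accuracy); cases with
    u > u* are flagged at the threshold's severity level.
    """
    b = reg["b"]
    if b >= 0:
        raise ValueError("regression slope must be negative to derive an uncertainty cut-off")
    return float((dc_threshold - reg["a"]) / b)


def fit_failure_model(
    uncertainties: Sequence[float],
    dcs: Sequence[float],
    *,
    structure_id: int | str = "all_structures_average",
) -> FailureModel:
    """Fit thresholds, regression, cut-offs and AUROCs for one structure
    (or for per-case all-structure averages).  Degenerate DC spread
    (MAD = 0) is rejected with a warning, as thresholds collapse onto the
    median there."""
    d = np.asarray(dcs, dtype=np.float64)
    med = float(np.median(d))
    mad = float(np.median(np.abs(d - med)))
    if mad == 0:
        warnings.warn(f"structure {structure_id}: MAD of DC is 0; thresholds degenerate", stacklevel=2)
    thr2 = mad_threshold(d, K_INACCURATE)
    thr3 = mad_threshold(d, K_FAILED)
    reg = fit_dc_uncertainty_regression(uncertainties, d)
    u2 = uncertainty_threshold_from_regression(reg, thr2)
    u3 = uncertainty_threshold_from_regression(reg, thr3)
    return FailureModel(
        structure_id=structure_id,
        dc_median=med,
        dc_mad=mad,
        dc_threshold_k2=thr2,
        dc_threshold_k3=thr3,
        regression_intercept=reg["a"],
        regression_slope=reg["b"],
        pearson_rho=reg["pearson_rho"],
        uncertainty_threshold_k2=u2,
        uncertainty_threshold_k3=u3,
        auroc_k2=detect_auroc(uncertainties, d, thr2),
        auroc_k3=detect_auroc(uncertainties, d, thr3),
        n=reg["n"],
    )


def screen_unlabeled(
    case_uncertainties: Mapping[str, Mapping[int, float]],
    model: FailureModel,
) -> list[dict]:
    """Screen unannotated cases by their mean structure uncertainty.

    ``case_uncertainties`` maps case id -> {structure_id: uncertainty}
    (NaN marks a structure absent from the prediction).  Each case is
    flagged ok / inaccurate / failed by comparing its all-structure mean
    uncertainty with the regression-derived cut-offs; a case with any
    missing structure is flagged failed outright.  The two flagged sets
    are nested (failed cases are also beyond the inaccurate cut-off
    whenever the regression slope is negative); each case reports its most
    severe flag.
    """
    report = []
    for case, per_struct in case_uncertainties.items():
        vals = np.array(list(per_struct.values()), dtype=np.float64)
        missing = [s for s, v in per_struct.items() if not np.isfinite(v)]
        mean_u = float(np.nanmean(vals)) if np.any(np.isfinite(vals)) else float("nan")
        if missing or not np.isfinite(mean_u):
            flag, reason = "failed", f"missing structures: {missing or 'all'}"
        elif mean_u > model.uncertainty_threshold_k3:
            flag, reason = "failed", "uncertainty above failed cut-off"
        elif mean_u > model.uncertainty_threshold_k2:
            flag, reason = "inaccurate", "uncertainty above inaccurate cut-off"
        else:
            flag, reason = "ok", ""
        report.append({"case": case, "mean_uncertainty": mean_u, "flag": flag, "reason": reason})
    return report
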