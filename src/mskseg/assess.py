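"""Per-structure biomarkers: volume, height-normalized volume, mean HU,
and lean/composite/fat density composition.

Volume is voxel count x voxel volume in cc; the normalized volume divides
by height^e (e defaults to 2, giving cc/m^2; e=1 gives cc/m — both unit
strings are always emitted so the convention is never silent).  Muscle
density is the unweighted mean of the raw HU values inside the label.
Tissue classes follow the standard HU bands: fat < -30 HU, muscle/fat
composite in [-30, 30] (closed on both ends), lean muscle > 30 HU.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .phantom import CTVolume
from .postprocess import SideResolvedLabelMap, side_code

__all__ = [
    "StructureMeasure",
    "measure_structure",
    "measure_all",
    "classify_density",
    "density_render_table",
    "FAT_HU",
    "LEAN_HU",
]

FAT_HU = -30.0  # below: fat
LEAN_HU = 30.0  # above: lean muscle; [-30, 30] is composite


@dataclass
class StructureMeasure:
    structure_id: int
    side: str
    voxel_count: int
    volume_cc: float
    normalized_volume: float | None  # None flagged when height missing
    normalization_exponent: int
    normalized_volume_unit: str
    mean_hu: float
    density_fractions: Mapping[str, float]
    histogram: pd.DataFrame  # columns: hu_lo, hu_hi, count
    missing: bool = False


def classify_density(hu: float) -> str:
    """HU band of a single value: 'fat', 'composite' or 'lean'."""
    if not np.isfinite(hu):
        raise ValueError("HU value must be finite")
    if hu < FAT_HU:
        return "fat"
    if hu > LEAN_HU:
        return "lean"
    return "composite"


def _density_fractions(hu: np.ndarray) -> dict[str, float]:
    n = hu.size
    fat = int((hu < FAT_HU).sum())
    lean = int((hu > LEAN_HU).sum())
    comp = n - fat - lean
    return {"fat": fat / n, "composite": comp / n, "lean": lean / n}


def measure_structure(
    vol: CTVolume,
    lab: SideResolvedLabelMap,
    structure_id: int,
    side: str,
    *,
    normalization_exponent: int = 2,
    histogram_range: tuple[float, float] = (-200.0, 200.0),
    histogram_bin_hu: float = 1.0,
) -> StructureMeasure:
    """Biomarkers of one structure instance; flags (not raises) absence."""
    if vol.voxels.shape != lab.labels.shape:
        raise ValueError("volume and label grids differ")
    unit = f"cc/m^{normalization_exponent}" if normalization_exponent != 1 else "cc/m"
    mask = lab.labels == side_code(structure_id, side)
    n = int(mask.sum())
    if n == 0:
        return StructureMeasure(
            structure_id, side, 0, 0.0, None, normalization_exponent, unit,
            float("nan"), {}, pd.DataFrame(columns=["hu_lo", "hu_hi", "count"]), missing=True,
        )
    hu = vol.voxels[mask].astype(np.float64)
    volume_cc = n * vol.voxel_volume_cc
    if vol.height_m is None:
        normalized = None
    else:
        normalized = volume_cc / vol.height_m**normalization_exponent
    edges = np.arange(histogram_range[0], histogram_range[1] + histogram_bin_hu, histogram_bin_hu)
    counts, _ = np.histogram(hu, bins=edges)
    hist = pd.DataFrame({"hu_lo": edges[:-1], "hu_hi": edges[1:], "count": counts})
    return StructureMeasure(
        structure_id=structure_id,
        side=side,
        voxel_count=n,
        volume_cc=volume_cc,
        normalized_volume=normalized,
        normalization_exponent=normalization_exponent,
        normalized_volume_unit=unit,
        mean_hu=float(hu.mean()),
        density_fractions=_density_fractions(hu),
        histogram=hist,
    )


def measure_all(vol: CTVolume, lab: SideResolvedLabelMap, **kwargs) -> pd.DataFrame:
    """Long-format table of measures for every instance in the code table."""
    rows = []
    for code, (sid, side) in sorted(lab.code_table.items()):
        m = measure_structure(vol, lab, sid, side, **kwargs)
        rows.append(
            {
                "subject": vol.subject_id,
                "structure": sid,
                "side": side,
                "voxel_count": m.voxel_count,
                "volume_cc": m.volume_cc,
                "normalized_volume": m.normalized_volume,
                "normalized_volume_unit": m.normalized_volume_unit,
                "mean_hu": m.mean_hu,
                "frac_fat": m.density_fractions.get("fat", np.nan),
                "frac_composite": m.density_fractions.get("composite", np.nan),
                "frac_lean": m.density_fractions.get("lean", np.nan),
            }
        )
    return pd.DataFrame(rows)


def density_render_table(
    measure: StructureMeasure | None = None,
    *,
    hu_support: tuple[float, float] = (-200.0, 200.0),
    n_points_per_segment: int = 8,
) -> pd.DataFrame:
    """Color/opacity transfer function for muscle-density volume rendering.

    Piecewise mapping over HU with breakpoints at exactly -30 and +30:
    fat renders in a yellow ramp, composite in orange, lean muscle in a red
    ramp; opacity is 0 outside the HU support.  Deterministic; the measure
    argument is accepted only so callers can keep table and measure
    together, the mapping itself depends on nothing but the breakpoints.
    """
    lo, hi = hu_support
    if not lo < FAT_HU < LEAN_HU < hi:
        raise ValueError("hu_support must bracket the -30/+30 breakpoints")
    rows = [(lo, 0.0, 0.0, 0.0, 0.0)]  # transparent below support
    segments = [
        (lo, FAT_HU, (1.0, 1.0, 0.2), (1.0, 0.85, 0.0)),  # fat: yellow ramp
        (FAT_HU, LEAN_HU, (1.0, 0.75, 0.1), (1.0, 0.45, 0.1)),  # composite: orange
        (LEAN_HU, hi, (0.9, 0.25, 0.1), (0.6, 0.0, 0.0)),  # lean: red ramp
    ]
    for a, b, c0, c1 in segments:
        ts = np.linspace(0.0, 1.0, n_points_per_segment)
        for t in ts:
            hu = a + t * (b - a)
            r, g, bl = (np.array(c0) * (1 - t) + np.array(c1) * t).tolist()
            opacity = 0.2 + 0.6 * (hu - lo) / (hi - lo)
            rows.append((hu, r, g, bl, opacity))
    rows.append((hi, 0.0, 0.0, 0.0, 0.0))  # transparent above support
    df = pd.DataFrame(rows, columns=["hu", "r", "g", "b", "opacity"])
    return df
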