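"""Synthetic bilateral CT phantoms with ground-truth labels.

Volumes use the axis convention (z, y, x): axial slices are indexed by z
and the left-right axis is x (patient left = +x).  Each phantom contains
``n_structures`` mirror-placed ellipsoid pairs plus one midline ellipsoid,
each with its own Hounsfield-unit distribution, embedded in a water-like
background with additive Gaussian noise.  An optional thin cylindrical
bridge can connect the first pair across the midline (the analogue of two
hemi-pelvises meeting at the pubic symphysis), and a corruption operator
collapses structure/background contrast to emulate domain shift or severe
disease, degrading segmentability in a controlled way.

The generated label map is side-resolved: pair ``i`` (0-based) uses code
``2*i+1`` on the left and ``2*i+2`` on the right; the midline structure
uses ``2*n_structures+1``.  ``merge_sides`` collapses these to the
per-structure classes (pair ``i`` -> ``i+1``, midline -> ``n+1``) that the
segmentation model is trained on; recovering sides afterwards is the job
of the postprocessing module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "PhantomSpec",
    "CTVolume",
    "LabelMap",
    "PackingError",
    "generate_phantom",
    "corrupt_phantom",
    "merge_sides",
    "pair_codes",
    "midline_code",
]

HU_MIN, HU_MAX = -1024.0, 3071.0


@dataclass(frozen=True)
class PhantomSpec:
    """Study conditions for one synthetic subject."""

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_structures: int = 3  # mirror pairs; one midline structure is added
    hu_means: Sequence[float] = (60.0, 45.0, -100.0, 300.0)  # pairs..., midline
    hu_sd: Sequence[float] | float = 10.0
    noise_sd: float = 20.0
    shape_jitter: float = 0.1
    bridge_prob: float = 0.0
    corruption_level: float = 0.0
    background_hu: float = 0.0
    height_m: float = 1.70
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing components must be > 0")
        if any(g < 8 for g in self.grid_shape):
            raise ValueError("grid_shape components must be >= 8")
        if len(self.hu_means) != self.n_structures + 1:
            raise ValueError("hu_means must have n_structures + 1 entries (pairs then midline)")
        if any(not HU_MIN <= m <= HU_MAX for m in self.hu_means):
            raise ValueError(f"hu_means must lie within [{HU_MIN}, {HU_MAX}]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.corruption_level <= 1.0:
            raise ValueError("corruption_level must be in [0,1]")

    @property
    def hu_sds(self) -> np.ndarray:
        sd = np.broadcast_to(np.asarray(self.hu_sd, dtype=float), (self.n_structures + 1,))
        if np.any(sd < 0):
            raise ValueError("hu_sd must be >= 0")
        return sd


@dataclass
class CTVolume:
    """A 3D HU grid with physical spacing and subject metadata."""

    voxels: np.ndarray  # (Z, Y, X) float
    spacing_mm: tuple[float, float, float]
    height_m: float | None = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxel values must be finite")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be strictly positive")

    @property
    def voxel_volume_cc(self) -> float:
        return float(np.prod(self.spacing_mm)) / 1000.0


@dataclass
class LabelMap:
    """Integer structure map on the same grid as its CTVolume.

    ``side_codes`` maps each nonzero code to ``(structure_id, side)`` with
    side in {"left", "right", "midline"}; present only when the map is
    side-resolved.  ``meta`` carries generator provenance such as analytic
    ellipsoid volumes.
    """

    labels: np.ndarray  # (Z, Y, X) int
    side_codes: Mapping[int, tuple[int, str]] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if self.labels.min() < 0:
            raise ValueError("labels must be nonnegative")

    def codes(self) -> np.ndarray:
        u = np.unique(self.labels)
        return u[u > 0]


class PackingError(RuntimeError):
    """Raised when a structure cannot be placed without overlap."""


def pair_codes(i: int) -> tuple[int, int]:
    """(left, right) side-resolved codes of 0-based pair ``i``."""
    return 2 * i + 1, 2 * i + 2


def midline_code(n_structures: int) -> int:
    return 2 * n_structures + 1


def _layout(spec: PhantomSpec) -> list[dict]:
    """Nominal (pre-jitter) centers and radii in voxel units.

    Structure rows are stacked along y; pairs sit at x = center +/- 0.22*X,
    the midline structure on the midsagittal plane itself.
    """
    nz, ny, nx = spec.grid_shape
    n = spec.n_structures
    rows = [(i + 1) * ny / (n + 2) for i in range(n + 1)]
    xc = (nx - 1) / 2.0
    off = 0.22 * nx
    rz, ry, rx = 0.30 * nz, 0.40 * ny / (n + 2), 0.15 * nx
    out = []
    for i in range(n):
        for side, sgn in (("left", +1), ("right", -1)):
            out.append(
                {
                    "pair": i,
                    "side": side,
                    "code": pair_codes(i)[0] if side == "left" else pair_codes(i)[1],
                    "center": np.array([(nz - 1) / 2.0, rows[i], xc + sgn * off]),
                    "radii": np.array([rz, ry, rx]),
                }
            )
    out.append(
        {
            "pair": n,
            "side": "midline",
            "code": midline_code(n),
            "center": np.array([(nz - 1) / 2.0, rows[n], xc]),
            "radii": np.array([rz, ry, rx]),
        }
    )
    return out


def _ellipsoid_mask(shape: tuple[int, int, int], center: np.ndarray, radii: np.ndarray) -> np.ndarray:
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    d = (
        ((zz - center[0]) / radii[0]) ** 2
        + ((yy - center[1]) / radii[1]) ** 2
        + ((xx - center[2]) / radii[2]) ** 2
    )
    return d <= 1.0


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, LabelMap]:
    """Generate one phantom; a pure function of the spec (incl. its seed).

    Pair jitter is drawn once per pair and shared by both sides, so the
    label map is exactly mirror-symmetric about the midsagittal plane
    (x -> X-1-x) for any jitter level.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.grid_shape
    structs = _layout(spec)
    j = spec.shape_jitter
    # one jitter draw per pair (shared across sides) + one for the midline
    jit = {}
    for i in range(spec.n_structures + 1):
        jit[i] = {
            "radii": 1.0 + rng.uniform(-j, j, size=3),
            "dz": rng.uniform(-j, j) * structs[0]["radii"][0],
            "dy": rng.uniform(-j, j) * structs[0]["radii"][1],
        }
    bridge_fires = rng.random() < spec.bridge_prob

    labels = np.zeros(shape, dtype=np.int32)
    analytic_cc: dict[int, float] = {}
    for s in structs:
        jj = jit[s["pair"]]
        placed = False
        shrink = 1.0
        for _ in range(8):
            radii = s["radii"] * jj["radii"] * shrink
            center = s["center"] + np.array([jj["dz"], jj["dy"], 0.0])
            mask = _ellipsoid_mask(shape, center, radii)
            if not np.any(labels[mask]):
                labels[mask] = s["code"]
                analytic_cc[s["code"]] = float(
                    4.0 / 3.0 * np.pi * np.prod(radii) * np.prod(spec.spacing_mm) / 1000.0
                )
                placed = True
                break
            shrink *= 0.9
        if not placed:
            raise PackingError(f"could not place structure pair={s['pair']} side={s['side']}")

    bridge_voxels = 0
    if bridge_fires and spec.n_structures >= 1:
        left, right = structs[0], structs[1]
        jj = jit[0]
        c = left["center"] + np.array([jj["dz"], jj["dy"], 0.0])
        rzc = 0.35 * left["radii"][0] * jj["radii"][0]
        ryc = 0.35 * left["radii"][1] * jj["radii"][1]
        zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
        lo = min(left["center"][2], right["center"][2])
        hi = max(left["center"][2], right["center"][2])
        tube = (((zz - c[0]) / rzc) ** 2 + ((yy - c[1]) / ryc) ** 2 <= 1.0) & (xx >= lo) & (xx <= hi)
        new = tube & (labels == 0)
        xmid = (shape[2] - 1) / 2.0
        xs = np.broadcast_to(np.arange(shape[2]), shape)
        labels[new & (xs > xmid)] = pair_codes(0)[0]
        labels[new & (xs <= xmid)] = pair_codes(0)[1]
        bridge_voxels = int(new.sum())

    # intensities: background + per-structure HU draws + stationary noise
    vox = np.full(shape, spec.background_hu, dtype=np.float64)
    sds = spec.hu_sds
    for s in structs:
        m = labels == s["code"]
        vox[m] = spec.hu_means[s["pair"]] + sds[s["pair"]] * rng.standard_normal(int(m.sum()))
    if spec.noise_sd > 0:
        vox += spec.noise_sd * rng.standard_normal(shape)
    np.clip(vox, HU_MIN, HU_MAX, out=vox)

    side_codes = {s["code"]: (s["pair"] + 1, s["side"]) for s in structs}
    vol = CTVolume(vox, spec.spacing_mm, height_m=spec.height_m, subject_id=f"phantom-{spec.seed}")
    lab = LabelMap(
        labels,
        side_codes=side_codes,
        meta={
            "analytic_volume_cc": analytic_cc,
            "bridge": bridge_fires,
            "bridge_voxels": bridge_voxels,
            "n_structures": spec.n_structures,
        },
    )
    if spec.corruption_level > 0:
        vol = corrupt_phantom(vol, lab, spec.corruption_level, seed=spec.seed + 1)
    return vol, lab


def corrupt_phantom(vol: CTVolume, lab: LabelMap, level: float, seed: int = 0) -> CTVolume:
    """Collapse structure/background contrast by ``level`` in [0,1].

    Each labeled voxel value v is replaced by (1-level)*v + level*b with b
    drawn from a Gaussian fitted to the background voxels, so level=0 is
    the identity and level=1 makes structures statistically indistinguishable
    from background.  The surrogate for disease/domain-shift severity.
    """
    if not 0.0 <= level <= 1.0:
        raise ValueError(f"corruption level must be in [0,1], got {level}")
    if level == 0.0:
        return CTVolume(vol.voxels.copy(), vol.spacing_mm, vol.height_m, vol.subject_id)
    bg = vol.voxels[lab.labels == 0]
    mu, sd = float(bg.mean()), float(bg.std())
    rng = np.random.default_rng(seed)
    out = vol.voxels.astype(np.float64).copy()
    m = lab.labels > 0
    b = mu + sd * rng.standard_normal(int(m.sum()))
    out[m] = (1.0 - level) * out[m] + level * b
    return CTVolume(out, vol.spacing_mm, vol.height_m, vol.subject_id)


def merge_sides(lab: LabelMap) -> LabelMap:
    """Collapse side-resolved codes to per-structure classes.

    Pair i (codes 2i+1, 2i+2) -> class i+1; midline keeps its own class.
    Requires ``side_codes``.
    """
    if lab.side_codes is None:
        raise ValueError("label map is not side-resolved")
    out = np.zeros_like(lab.labels)
    for code, (sid, _side) in lab.side_codes.items():
        out[lab.labels == code] = sid
    return LabelMap(out, side_codes=None, meta=dict(lab.meta))
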