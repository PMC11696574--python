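"""Monte-Carlo dropout sampling (MCDS) and uncertainty aggregation.

At test time the trained U-Net is run T times per volume with dropout
active; the per-voxel mean of the sampled class probabilities yields the
fused label (argmax), and the variance across samples of the fused class's
probability yields the voxel-wise uncertainty map.  The structure-wise
predictive uncertainty is the average of that map over the *predicted*
voxels of each structure.  An entropy mode computes -sum p ln p from a
single deterministic (dropout-off) pass instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .model import TrainedModel, normalize_hu
from .phantom import CTVolume, LabelMap

__all__ = [
    "McdsConfig",
    "UncertaintyResult",
    "mcds_predict",
    "mcds_sample_probs",
    "fuse_samples",
    "entropy_map",
    "structure_uncertainty",
    "MISSING",
]

#: sentinel for "structure absent from the prediction" — an absent structure
#: is itself a failure signal and must never be read as zero uncertainty.
MISSING = float("nan")


@dataclass(frozen=True)
class McdsConfig:
    n_samples: int = 10
    uncertainty_kind: str = "variance"  # variance | entropy
    per_class_variance: bool = True  # mean over classes; False: fused-class only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.uncertainty_kind not in ("variance", "entropy"):
            raise ValueError(f"unknown uncertainty_kind {self.uncertainty_kind!r}")


@dataclass
class UncertaintyResult:
    label_map: LabelMap
    voxel_uncertainty: np.ndarray  # (Z, Y, X) float, >= 0
    structure_uncertainty: Mapping[int, float]
    n_samples_used: int
    uncertainty_kind: str = "variance"
    mean_probs: np.ndarray | None = field(default=None, repr=False)  # (Z,K,Y,X)


def _sample_rng(seed: int, sample_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(sample_index,)))


def mcds_sample_probs(model: TrainedModel, vol: CTVolume, cfg: McdsConfig) -> np.ndarray:
    """Raw MC samples: (T, Z, K, Y, X) float32 probability stacks.

    Sample t uses its own RNG stream derived from (cfg.seed, t); all axial
    slices of the volume are processed in one batched pass per sample, in
    fixed z order, so results are reproducible for a given seed.
    """
    if not model.has_dropout:
        raise ValueError("model has no dropout layers; MC dropout sampling is undefined")
    x = normalize_hu(vol.voxels, model.config.input_window_hu)
    out = np.empty((cfg.n_samples,) + (x.shape[0], model.config.n_classes) + x.shape[1:], dtype=np.float32)
    for t in range(cfg.n_samples):
        out[t] = model.predict_slices(x, stochastic=True, rng=_sample_rng(cfg.seed, t))
    return out


def fuse_samples(
    samples: np.ndarray, *, per_class_variance: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fuse (T, Z, K, Y, X) samples -> (labels, voxel variance, mean probs).

    Labels are the argmax of the mean probability; the variance map is,
    per voxel, the mean over classes of the population (1/T) variance of
    each class's probability across samples -- this captures inter-class
    competition that the winning channel alone can miss.  Setting
    ``per_class_variance=False`` restricts the variance to the fused
    (argmax) class's probability.
    """
    mean = samples.mean(axis=0)  # (Z, K, Y, X)
    labels = mean.argmax(axis=1).astype(np.int32)  # (Z, Y, X)
    if per_class_variance:
        var = samples.var(axis=0).mean(axis=1)
    else:
        fused = np.take_along_axis(samples, labels[None, :, None, :, :], axis=2)[:, :, 0]
        var = fused.var(axis=0)
    return labels, var.astype(np.float64), mean


def entropy_map(probs: np.ndarray, axis: int = 1) -> np.ndarray:
    """Per-voxel Shannon entropy -sum_k p_k ln p_k (nats) of a probability
    field; maximal at ln(K) for a uniform distribution over K classes."""
    p = np.clip(np.asarray(probs, dtype=np.float64), 1e-12, 1.0)
    return -(p * np.log(p)).sum(axis=axis)


def mcds_predict(model: TrainedModel, vol: CTVolume, cfg: McdsConfig) -> UncertaintyResult:
    """Segment a CT volume with MCDS uncertainty (the standard setting
    is T=10 variance fusion; ``uncertainty_kind='entropy'`` instead runs a
    single deterministic pass and reports the per-voxel entropy in nats)."""
    if cfg.uncertainty_kind == "entropy":
        x = normalize_hu(vol.voxels, model.config.input_window_hu)
        probs = model.predict_slices(x, stochastic=False)  # (Z, K, Y, X)
        labels = probs.argmax(axis=1).astype(np.int32)
        voxel_unc = entropy_map(probs)
        mean = probs
        n_used = 1
    else:
        samples = mcds_sample_probs(model, vol, cfg)
        labels, voxel_unc, mean = fuse_samples(samples, per_class_variance=cfg.per_class_variance)
        n_used = cfg.n_samples
    lab = LabelMap(labels)
    result = UncertaintyResult(
        label_map=lab,
        voxel_uncertainty=voxel_unc,
        structure_uncertainty={},
        n_samples_used=n_used,
        uncertainty_kind=cfg.uncertainty_kind,
        mean_probs=mean,
    )
    structures = [int(c) for c in range(1, model.config.n_classes)]
    result.structure_uncertainty = {c: structure_uncertainty(result, c) for c in structures}
    return result


def structure_uncertainty(result: UncertaintyResult, structure_id: int) -> float:
    """Mean voxel uncertainty over the *predicted* voxels of a structure.

    Returns NaN (flagged missing) when the structure has no predicted
    voxels — absence is a failure signal, never silently zero.
    """
    m = result.label_map.labels == structure_id
    n = int(m.sum())
    if n == 0:
        return MISSING
    return float(result.voxel_uncertainty[m].mean())
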