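"""Desk-scale end-to-end studies on synthetic phantom cohorts.

These functions reproduce the pipeline's study designs at CPU scale:
train a reduced Bayesian U-Net on uncorrupted phantoms, apply MC-dropout
inference to a held-out cohort containing contrast-corrupted cases,
evaluate per-structure accuracy and uncertainty, and fit/score the
failure-detection model.  The dropout-sample plateau study fuses nested
prefixes of one MC sample stack, so T=1/10/20 share their random draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluate import aie, asd, ave, dice
from .failure import fit_failure_model, mad_threshold, K_INACCURATE
from .inference import McdsConfig, fuse_samples, mcds_sample_probs
from .model import ModelConfig, TrainConfig, TrainedModel, build_model, train
from .phantom import CTVolume, LabelMap, PhantomSpec, generate_phantom, merge_sides
from .postprocess import split_sides

__all__ = ["ExperimentConfig", "make_cohort", "run_failure_detection_experiment", "dropout_plateau"]


@dataclass(frozen=True)
class ExperimentConfig:
    """Study conditions of the scaled failure-detection experiment."""

    n_train: int = 15
    n_test: int = 25
    n_corrupt: int = 10
    corruption_range: tuple[float, float] = (0.7, 0.9)
    # the annotated training cohort spans mild-to-moderate disease severity,
    # like a clinical training database; severe corruption stays unseen
    train_corruption_range: tuple[float, float] = (0.0, 0.5)
    grid_shape: tuple[int, int, int] = (16, 64, 64)
    spacing_mm: tuple[float, float, float] = (3.0, 1.5, 1.5)
    n_structures: int = 3
    n_iterations: int = 800
    batch_size: int = 3
    base_channels: int = 8
    n_encoder_layers: int = 5
    learning_rate: float = 1e-3
    n_mc_samples: int = 10
    seed: int = 0

    @property
    def n_classes(self) -> int:
        return self.n_structures + 2  # background + pairs + midline


def make_cohort(
    cfg: ExperimentConfig, n: int, *, corruption_levels: list[float] | None = None, seed_offset: int = 0
) -> list[tuple[CTVolume, LabelMap, float]]:
    """Generate n phantoms; entry i gets corruption level levels[i] (0 = clean)."""
    rng = np.random.default_rng(cfg.seed + seed_offset)
    cohort = []
    for i in range(n):
        level = 0.0 if corruption_levels is None else float(corruption_levels[i])
        spec = PhantomSpec(
            grid_shape=cfg.grid_shape,
            spacing_mm=cfg.spacing_mm,
            n_structures=cfg.n_structures,
            corruption_level=level,
            height_m=float(rng.uniform(1.50, 1.90)),
            seed=int(rng.integers(2**31 - 1)),
        )
        vol, lab = generate_phantom(spec)
        cohort.append((vol, lab, level))
    return cohort


def _case_records(
    subject_id: str,
    vol: CTVolume,
    gt_side: LabelMap,
    pred_labels: np.ndarray,
    voxel_unc: np.ndarray,
    cfg: ExperimentConfig,
    level: float,
) -> list[dict]:
    """Side-resolved per-structure accuracy + uncertainty records."""
    paired = set(range(1, cfg.n_structures + 1))
    pred_side = split_sides(LabelMap(pred_labels), paired, spacing_mm=cfg.spacing_mm)
    records = []
    for code, (sid, side) in sorted(gt_side.side_codes.items()):
        gt_mask = gt_side.labels == code
        if side == "midline":
            pred_mask = pred_side.labels == 2 * sid
        else:
            pred_mask = pred_side.mask(sid, side)
        dc = dice(gt_mask, pred_mask)
        n_pred = int(pred_mask.sum())
        if n_pred and gt_mask.any():
            asd_mm = asd(gt_mask, pred_mask, cfg.spacing_mm)
            gt_vol = gt_mask.sum() * vol.voxel_volume_cc
            pr_vol = n_pred * vol.voxel_volume_cc
            ave_pct = ave(gt_vol, pr_vol)
            aie_hu = aie(float(vol.voxels[gt_mask].mean()), float(vol.voxels[pred_mask].mean()))
            unc = float(voxel_unc[pred_mask].mean())
        else:  # absent prediction: accuracy floor, uncertainty flagged missing
            asd_mm, ave_pct, aie_hu, unc = np.nan, 100.0, np.nan, np.nan
        records.append(
            {
                "subject": subject_id,
                "structure": sid,
                "side": side,
                "dc": dc,
                "asd_mm": asd_mm,
                "ave_pct": ave_pct,
                "aie_hu": aie_hu,
                "uncertainty": unc,
                "corruption_level": level,
                "corrupted": level > 0,
            }
        )
    return records


def train_cohort_model(cfg: ExperimentConfig, cohort) -> TrainedModel:
    model_cfg = ModelConfig(
        n_classes=cfg.n_classes,
        n_encoder_layers=cfg.n_encoder_layers,
        base_channels=cfg.base_channels,
        seed=cfg.seed,
    )
    train_cfg = TrainConfig(
        n_iterations=cfg.n_iterations,
        batch_size=cfg.batch_size,
        learning_rate=cfg.learning_rate,
        seed=cfg.seed,
    )
    model = build_model(model_cfg)
    data = [(vol, merge_sides(lab)) for vol, lab, _ in cohort]
    return train(model, data, train_cfg)


def run_failure_detection_experiment(
    cfg: ExperimentConfig, *, collect_plateau: bool = False, plateau_ts: tuple[int, ...] = (1, 10, 20)
) -> dict:
    """Full scaled study for one seed.

    Returns records (DataFrame), the fitted all-structure FailureModel,
    the trained model, headline quantities, and (optionally) the
    dropout-sample plateau mean DCs keyed by T.
    """
    rng = np.random.default_rng(cfg.seed + 10_000)
    train_levels = [float(rng.uniform(*cfg.train_corruption_range)) for _ in range(cfg.n_train)]
    train_cohort = make_cohort(cfg, cfg.n_train, corruption_levels=train_levels, seed_offset=1)
    levels = [0.0] * (cfg.n_test - cfg.n_corrupt) + [
        float(rng.uniform(*cfg.corruption_range)) for _ in range(cfg.n_corrupt)
    ]
    rng.shuffle(levels)
    test_cohort = make_cohort(cfg, cfg.n_test, corruption_levels=levels, seed_offset=2)

    model = train_cohort_model(cfg, train_cohort)

    t_max = max(plateau_ts) if collect_plateau else cfg.n_mc_samples
    plateau_dcs: dict[int, list[float]] = {t: [] for t in plateau_ts}
    records: list[dict] = []
    for i, (vol, gt_side, level) in enumerate(test_cohort):
        samples = mcds_sample_probs(model, vol, McdsConfig(n_samples=t_max, seed=cfg.seed + 3))
        labels, voxel_unc, _ = fuse_samples(samples[: cfg.n_mc_samples])
        records.extend(_case_records(f"test-{i}", vol, gt_side, labels, voxel_unc, cfg, level))
        if collect_plateau and level == 0.0:
            gt_merged = merge_sides(gt_side)
            for t in plateau_ts:
                lab_t = samples[:t].mean(axis=0).argmax(axis=1)
                dcs = [
                    dice(gt_merged.labels == c, lab_t == c) for c in range(1, cfg.n_classes)
                ]
                plateau_dcs[t].append(float(np.mean(dcs)))

    df = pd.DataFrame(records)
    valid = df[np.isfinite(df["uncertainty"])]
    fm = fit_failure_model(valid["uncertainty"], valid["dc"])
    # per-case "all structures average" view (one point per subject, as in
    # a per-patient scatter of mean DC against mean predictive uncertainty);
    # missing structures count DC=0 but drop out of the uncertainty mean
    cases = (
        df.groupby("subject")
        .agg(dc=("dc", "mean"), uncertainty=("uncertainty", lambda u: np.nanmean(u)), corrupted=("corrupted", "any"))
        .reset_index()
    )
    fm_cases = fit_failure_model(cases["uncertainty"], cases["dc"])
    out = {
        "config": cfg,
        "records": df,
        "case_records": cases,
        "failure_model": fm,
        "failure_model_cases": fm_cases,
        "model": model,
        "mean_dc_uncorrupted": float(df.loc[~df["corrupted"], "dc"].mean()),
        "mean_dc_corrupted": float(df.loc[df["corrupted"], "dc"].mean()),
        "dc_threshold_k2": mad_threshold(df["dc"], K_INACCURATE),
    }
    if collect_plateau:
        out["plateau_mean_dc"] = {t: float(np.mean(v)) for t, v in plateau_dcs.items()}
    return out


def dropout_plateau(model: TrainedModel, cohort, ts: tuple[int, ...], seed: int, n_classes: int) -> dict[int, float]:
    """Mean Dice (merged classes, over cases) for each MC sample count in ts."""
    t_max = max(ts)
    per_t: dict[int, list[float]] = {t: [] for t in ts}
    for vol, gt_side, _level in cohort:
        samples = mcds_sample_probs(model, vol, McdsConfig(n_samples=t_max, seed=seed))
        gt_merged = merge_sides(gt_side)
        for t in ts:
            lab_t = samples[:t].mean(axis=0).argmax(axis=1)
            dcs = [dice(gt_merged.labels == c, lab_t == c) for c in range(1, n_classes)]
            per_t[t].append(float(np.mean(dcs)))
    return {t: float(np.mean(v)) for t, v in per_t.items()}
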