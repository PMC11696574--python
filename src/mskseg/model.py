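"""2D Bayesian U-Net: architecture, training loop and cross-validation.

The network processes CT volumes one axial slice at a time (the volume
result is the concatenation of per-slice outputs).  Each encoder level is
two basic blocks (same-padding 3x3 convolution -> optional batch norm ->
ReLU) followed by a dropout block; levels are joined by 2x2 max pooling.
Each decoder level is a 2x2 stride-2 up-convolution whose output is
concatenated with the matching encoder level's feature map, followed by
one basic block.  A 1x1 convolution and a softmax head yield per-pixel
class probabilities.  Keeping dropout active at inference turns repeated
forward passes into Monte-Carlo samples from an approximate posterior.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from . import nn
from .phantom import CTVolume, LabelMap

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "TrainedModel",
    "build_model",
    "train",
    "cross_validate",
    "normalize_hu",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyper-parameters of the Bayesian U-Net."""

    n_classes: int
    n_encoder_layers: int = 5
    base_channels: int = 64
    channel_growth: int = 2
    dropout_rate: float = 0.2
    use_batch_norm: bool = True
    input_window_hu: tuple[float, float] = (-150.0, 350.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_encoder_layers not in (5, 6):
            raise ValueError("n_encoder_layers must be 5 or 6")
        if not 0.0 < self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in (0,1)")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.input_window_hu[0] >= self.input_window_hu[1]:
            raise ValueError("input_window_hu must satisfy low < high")

    @property
    def n_decoder_layers(self) -> int:
        return self.n_encoder_layers - 1

    @property
    def channels(self) -> list[int]:
        return [self.base_channels * self.channel_growth**i for i in range(self.n_encoder_layers)]


@dataclass
class TrainConfig:
    """Optimisation settings; desk-scale defaults (full runs use far more)."""

    n_iterations: int = 500
    batch_size: int = 3
    learning_rate: float = 1e-3
    loss: str = "cross_entropy"  # cross_entropy | dice | combined
    augmentation: dict = field(default_factory=dict)  # {"flip_lr": bool}
    class_weights: Sequence[float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 1 or self.batch_size < 1:
            raise ValueError("n_iterations and batch_size must be >= 1")
        if self.loss not in ("cross_entropy", "dice", "combined"):
            raise ValueError(f"unknown loss {self.loss!r}")


def normalize_hu(voxels: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    """Linearly map the HU window to [0,1], clipping outside."""
    lo, hi = window
    return np.clip((voxels - lo) / (hi - lo), 0.0, 1.0).astype(np.float32)


class _UNet2D:
    """Layer graph with manual forward/backward bookkeeping."""

    def __init__(self, cfg: ModelConfig) -> None:
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        ch = cfg.channels
        self.enc_blocks: list[list[nn.Layer]] = []
        self.dropouts: list[nn.Dropout] = []
        self.pools: list[nn.MaxPool2d] = []
        c_prev = 1
        for lvl in range(cfg.n_encoder_layers):
            block: list[nn.Layer] = []
            for j in range(2):
                block.append(nn.Conv2d(c_prev if j == 0 else ch[lvl], ch[lvl], rng))
                if cfg.use_batch_norm:
                    block.append(nn.BatchNorm2d(ch[lvl]))
                block.append(nn.ReLU())
            drop = nn.Dropout(cfg.dropout_rate)
            block.append(drop)
            self.dropouts.append(drop)
            self.enc_blocks.append(block)
            c_prev = ch[lvl]
        self.pools = [nn.MaxPool2d() for _ in range(cfg.n_encoder_layers - 1)]
        self.upconvs: list[nn.ConvTranspose2d] = []
        self.dec_blocks: list[list[nn.Layer]] = []
        for lvl in range(cfg.n_encoder_layers - 2, -1, -1):
            self.upconvs.append(nn.ConvTranspose2d(c_prev, ch[lvl], rng))
            block = [nn.Conv2d(2 * ch[lvl], ch[lvl], rng)]
            if cfg.use_batch_norm:
                block.append(nn.BatchNorm2d(ch[lvl]))
            block.append(nn.ReLU())
            self.dec_blocks.append(block)
            c_prev = ch[lvl]
        self.head = nn.Conv2d1x1(c_prev, cfg.n_classes, rng)

    # -- plumbing ---------------------------------------------------------
    def layers(self) -> list[nn.Layer]:
        out: list[nn.Layer] = []
        for b in self.enc_blocks:
            out.extend(b)
        out.extend(self.pools)
        for up, b in zip(self.upconvs, self.dec_blocks):
            out.append(up)
            out.extend(b)
        out.append(self.head)
        return out

    def n_parameters(self) -> int:
        return sum(l.n_parameters() for l in self.layers())

    def _pad_input(self, x: np.ndarray) -> tuple[np.ndarray, tuple[int, int]]:
        div = 2 ** (self.cfg.n_encoder_layers - 1)
        h, w = x.shape[2], x.shape[3]
        ph = (-h) % div
        pw = (-w) % div
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)))
        return x, (ph, pw)

    def forward(self, x: np.ndarray, *, training: bool, rng: np.random.Generator | None) -> np.ndarray:
        """Logits of shape (N, n_classes, H, W); pads/crops internally."""
        x, (ph, pw) = self._pad_input(x.astype(np.float32))
        self.last_padding = (ph, pw)
        skips = []
        for lvl, block in enumerate(self.enc_blocks):
            for layer in block:
                x = layer.forward(x, training=training, rng=rng)
            if lvl < len(self.pools):
                skips.append(x)
                x = self.pools[lvl].forward(x, training=training, rng=rng)
        self._skip_channels = [s.shape[1] for s in skips]
        for i, (up, block) in enumerate(zip(self.upconvs, self.dec_blocks)):
            x = up.forward(x, training=training, rng=rng)
            skip = skips[-(i + 1)]
            x = np.concatenate([skip, x], axis=1)
            for layer in block:
                x = layer.forward(x, training=training, rng=rng)
        logits = self.head.forward(x, training=training, rng=rng)
        if ph or pw:
            logits = logits[:, :, : logits.shape[2] - ph, : logits.shape[3] - pw]
        return logits

    def backward(self, dlogits: np.ndarray) -> None:
        ph, pw = self.last_padding
        if ph or pw:
            dlogits = np.pad(dlogits, ((0, 0), (0, 0), (0, ph), (0, pw)))
        g = self.head.backward(dlogits)
        # decoder i consumed encoder level (L-2-i)'s skip; walk decoders in
        # reverse creation order so skip_grads[k] ends up keyed by level k
        skip_grads: dict[int, np.ndarray] = {}
        for i in range(len(self.dec_blocks) - 1, -1, -1):
            for layer in reversed(self.dec_blocks[i]):
                g = layer.backward(g)
            lvl = len(self.enc_blocks) - 2 - i
            c_skip = self._skip_channels[lvl]
            skip_grads[lvl] = g[:, :c_skip]
            g = self.upconvs[i].backward(g[:, c_skip:])
        # g is now the gradient entering the bottleneck from below
        for lvl in range(len(self.enc_blocks) - 1, -1, -1):
            if lvl < len(self.pools):
                g = self.pools[lvl].backward(g)
                g = g + skip_grads[lvl]
            for layer in reversed(self.enc_blocks[lvl]):
                g = layer.backward(g)

    def set_dropout_active(self, active: bool) -> None:
        for d in self.dropouts:
            d.active = active


@dataclass
class TrainedModel:
    """A (possibly untrained) U-Net plus its config and training history."""

    config: ModelConfig
    net: _UNet2D
    training_log: list[float] = field(default_factory=list)

    @property
    def n_parameters(self) -> int:
        return self.net.n_parameters()

    @property
    def has_dropout(self) -> bool:
        return len(self.net.dropouts) > 0

    def predict_slices(
        self,
        slices: np.ndarray,
        *,
        stochastic: bool = False,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        """Class probabilities (N, K, H, W) for normalized input slices.

        With ``stochastic=True`` dropout stays active (one MC sample);
        batch-norm always uses running statistics at prediction time.
        """
        if slices.ndim == 2:
            slices = slices[None]
        x = slices[:, None, :, :]
        self.net.set_dropout_active(stochastic)
        try:
            logits = self.net.forward(x, training=False, rng=rng if stochastic else None)
        finally:
            self.net.set_dropout_active(True)
        return nn.softmax(logits, axis=1)

    # -- checkpointing ----------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        arrays: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.net.layers()):
            for k, v in layer.params.items():
                arrays[f"{i}.{k}"] = v
            if isinstance(layer, nn.BatchNorm2d):
                arrays[f"{i}.running_mean"] = layer.running_mean
                arrays[f"{i}.running_var"] = layer.running_var
        np.savez(path / "weights.npz", **arrays)
        (path / "config.json").write_text(json.dumps(asdict(self.config), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        path = Path(path)
        cfg_d = json.loads((path / "config.json").read_text())
        cfg_d["input_window_hu"] = tuple(cfg_d["input_window_hu"])
        cfg = ModelConfig(**cfg_d)
        model = build_model(cfg)
        with np.load(path / "weights.npz") as data:
            for i, layer in enumerate(model.net.layers()):
                for k in layer.params:
                    layer.params[k][...] = data[f"{i}.{k}"]
                if isinstance(layer, nn.BatchNorm2d):
                    layer.running_mean[...] = data[f"{i}.running_mean"]
                    layer.running_var[...] = data[f"{i}.running_var"]
        return model


def build_model(config: ModelConfig) -> TrainedModel:
    """Instantiate an untrained Bayesian U-Net for the given config."""
    return TrainedModel(config=config, net=_UNet2D(config))


def _soft_dice_grad(p: np.ndarray, target: np.ndarray, n_classes: int) -> tuple[float, np.ndarray]:
    """Soft multi-class Dice loss and its gradient w.r.t. logits."""
    n, k, h, w = p.shape
    onehot = np.zeros_like(p)
    idx = np.indices((n, h, w))
    onehot[idx[0], target, idx[1], idx[2]] = 1.0
    eps = 1e-6
    inter = (p * onehot).sum(axis=(0, 2, 3))
    denom = p.sum(axis=(0, 2, 3)) + onehot.sum(axis=(0, 2, 3))
    dice_k = (2 * inter + eps) / (denom + eps)
    loss = float(1.0 - dice_k.mean())
    # dL/dp_k = -(2*t*denom - (2*inter+eps)) / denom^2 / K
    dldp = -(2 * onehot * (denom + eps)[None, :, None, None] - (2 * inter + eps)[None, :, None, None] * 2) / (
        (denom + eps) ** 2
    )[None, :, None, None] / k
    dot = (dldp * p).sum(axis=1, keepdims=True)
    dlogits = p * (dldp - dot)
    return loss, dlogits.astype(np.float32)


def train(model: TrainedModel, data: Sequence[tuple[CTVolume, LabelMap]], cfg: TrainConfig) -> TrainedModel:
    """Train in place on axial slices sampled uniformly from ``data``.

    Labels must already be class codes in [0, n_classes); volumes are
    HU-windowed to [0,1] once up front.
    """
    if len(data) == 0:
        raise ValueError("empty training dataset")
    k = model.config.n_classes
    vols, labs = [], []
    for vol, lab in data:
        bad = np.setdiff1d(np.unique(lab.labels), np.arange(k))
        if bad.size:
            raise ValueError(f"label code {bad[0]} outside [0, {k})")
        vols.append(normalize_hu(vol.voxels, model.config.input_window_hu))
        labs.append(lab.labels.astype(np.int64))
    n_slices = [v.shape[0] for v in vols]
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(model.net.layers(), lr=cfg.learning_rate)
    weights = None if cfg.class_weights is None else np.asarray(cfg.class_weights, dtype=np.float64)
    flip = bool(cfg.augmentation.get("flip_lr", False))
    for _ in range(cfg.n_iterations):
        xs, ys = [], []
        for _ in range(cfg.batch_size):
            vi = rng.integers(len(vols))
            zi = rng.integers(n_slices[vi])
            x, y = vols[vi][zi], labs[vi][zi]
            if flip and rng.random() < 0.5:
                x, y = x[:, ::-1], y[:, ::-1]
            xs.append(x)
            ys.append(y)
        xb = np.stack(xs)[:, None, :, :]
        yb = np.stack(ys)
        logits = model.net.forward(xb, training=True, rng=rng)
        if cfg.loss == "cross_entropy":
            loss, dlogits = nn.softmax_cross_entropy(logits, yb, weights)
        elif cfg.loss == "dice":
            loss, dlogits = _soft_dice_grad(nn.softmax(logits, axis=1), yb, k)
        else:  # combined
            l1, g1 = nn.softmax_cross_entropy(logits, yb, weights)
            l2, g2 = _soft_dice_grad(nn.softmax(logits, axis=1), yb, k)
            loss, dlogits = l1 + l2, g1 + g2
        model.net.backward(dlogits)
        opt.step()
        model.training_log.append(loss)
    return model


def cross_validate(
    data: Sequence[tuple[CTVolume, LabelMap]],
    k_folds: int,
    cfg: TrainConfig,
    model_config: ModelConfig,
) -> list[dict]:
    """k-fold cross-validation; each subject is held out exactly once.

    Returns one record per fold with the trained model, held-out indices
    and deterministic (dropout-off) predicted label volumes.
    """
    n = len(data)
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    if k_folds > n:
        raise ValueError(f"k_folds={k_folds} exceeds dataset size {n}")
    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(n)
    folds = [sorted(order[i::k_folds].tolist()) for i in range(k_folds)]
    results = []
    for fi, held in enumerate(folds):
        train_idx = [i for i in range(n) if i not in held]
        model = build_model(model_config)
        train(model, [data[i] for i in train_idx], cfg)
        preds = {}
        for i in held:
            x = normalize_hu(data[i][0].voxels, model_config.input_window_hu)
            probs = model.predict_slices(x, stochastic=False)
            preds[i] = probs.argmax(axis=1).astype(np.int32)
        results.append({"fold": fi, "held_out": held, "model": model, "predictions": preds})
    return results
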