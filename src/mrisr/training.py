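"""Paired-data construction and the edge-weighted L1 training loop.

Truncating k-space removes high spatial frequencies, so edges are what
the degradation destroys and what the network must restore.  Training
therefore minimises an edge-weighted L1 objective::

    L = mean|pred - label| + lambda * mean|E(pred) - E(label)|

where ``E`` is the Sobel gradient magnitude (3x3 stencils, symmetric
boundary padding).  Optimisation uses Adam with a one-cycle learning
rate schedule; the checkpoint kept is the epoch with minimum validation
edge-L1, not the last epoch.

Training is staged: a 2x model is trained first, its weights are
transferred to a 4x model (fresh up-sampler stages) for further
training, and a fine-tune stage adapts to a new anatomy at a lower
learning rate.  The per-stage peak learning rates default to 1e-5
(scale2_base), 5e-5 (scale4_transfer) and 1e-6 (finetune).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import convolve2d, correlate2d

from .image import GrayImage
from .kspace_ops import kspace_downsample
from .nn import Adam
from .sr_core import EDSR, ModelBundle, bundle_from_model

__all__ = [
    "TrainConfig",
    "MetricLog",
    "STAGE_MAX_LR",
    "make_pair",
    "edge_map",
    "edge_l1_loss",
    "one_cycle_lr",
    "train_stage",
]

# Peak learning rate per training stage.
STAGE_MAX_LR = {"scale2_base": 1e-5, "scale4_transfer": 5e-5, "finetune": 1e-6}

_SOBEL_X = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]])
_SOBEL_Y = _SOBEL_X.T


@dataclass
class TrainConfig:
    """Hyperparameters of one training stage."""

    stage: str = "scale4_transfer"
    max_lr: float | None = None       # None -> stage default
    label_crop: int = 192
    batch: int = 16
    epochs: int = 30
    seed: int = 0
    edge_lambda: float = 1.0
    val_fraction: float = 0.1
    pct_start: float = 0.3
    div: float = 25.0
    final_div: float = 1e4

    def __post_init__(self) -> None:
        if self.stage not in STAGE_MAX_LR:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.max_lr is None:
            self.max_lr = STAGE_MAX_LR[self.stage]
        if self.max_lr <= 0:
            raise ValueError("max_lr must be positive")
        if self.edge_lambda < 0:
            raise ValueError("edge_lambda must be >= 0")


@dataclass
class MetricLog:
    """Per-epoch training metrics and the best-checkpoint pointer."""

    records: list[dict] = field(default_factory=list)

    def append(self, **kwargs) -> None:
        self.records.append(dict(kwargs))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @property
    def best_epoch(self) -> int:
        losses = [r["val_edge_l1"] for r in self.records]
        return int(np.argmin(losses))


def make_pair(label: GrayImage, crop: int, factor: int,
              rng: np.random.Generator) -> tuple[GrayImage, GrayImage]:
    """Random HR crop plus its k-space-truncated LR counterpart."""
    h, w = label.shape
    if crop > h or crop > w:
        raise ValueError(f"label {label.shape} smaller than crop {crop}")
    if crop % factor:
        raise ValueError("crop must be divisible by the scale factor")
    r0 = int(rng.integers(0, h - crop + 1))
    c0 = int(rng.integers(0, w - crop + 1))
    label_crop = GrayImage(label.pixels[r0:r0 + crop, c0:c0 + crop], label.spacing)
    lr = kspace_downsample(label_crop, factor)
    return lr, label_crop


def _sobel_pair(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    xp = np.pad(x, 1, mode="symmetric")
    gx = correlate2d(xp, _SOBEL_X, mode="valid")
    gy = correlate2d(xp, _SOBEL_Y, mode="valid")
    return gx, gy


def _sobel_adjoint(u: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Exact adjoint of pad-symmetric-then-valid-correlate."""
    vp = convolve2d(u, kernel, mode="full")
    vp[1] += vp[0]
    vp[-2] += vp[-1]
    vp[:, 1] += vp[:, 0]
    vp[:, -2] += vp[:, -1]
    return vp[1:-1, 1:-1]


def edge_map(img: GrayImage | np.ndarray) -> np.ndarray:
    """Sobel gradient-magnitude map (nonnegative, zero on constants)."""
    x = img.pixels if isinstance(img, GrayImage) else np.asarray(img, float)
    gx, gy = _sobel_pair(x)
    return np.hypot(gx, gy)


def edge_l1_loss(pred, label, edge_lambda: float = 1.0) -> float:
    """Mean absolute error plus ``lambda`` times edge-map MAE."""
    p = pred.pixels if isinstance(pred, GrayImage) else np.asarray(pred, float)
    l = label.pixels if isinstance(label, GrayImage) else np.asarray(label, float)
    if p.shape != l.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {l.shape}")
    if edge_lambda < 0:
        raise ValueError("edge_lambda must be >= 0")
    loss = float(np.mean(np.abs(p - l)))
    if edge_lambda > 0:
        loss += edge_lambda * float(np.mean(np.abs(edge_map(p) - edge_map(l))))
    return loss


def _edge_l1_loss_grad(pred: np.ndarray, label: np.ndarray,
                       edge_lambda: float, eps: float = 1e-8
                       ) -> tuple[float, np.ndarray]:
    """Loss and dL/dpred for one 2-D image (eps-smoothed magnitudes)."""
    n = pred.size
    diff = pred - label
    loss = float(np.mean(np.abs(diff)))
    grad = np.sign(diff) / n
    if edge_lambda > 0:
        gx, gy = _sobel_pair(pred)
        e_pred = np.sqrt(gx * gx + gy * gy + eps)
        e_label = edge_map(label)
        ediff = e_pred - e_label
        loss += edge_lambda * float(np.mean(np.abs(ediff)))
        s = np.sign(ediff) * (edge_lambda / n)
        grad += _sobel_adjoint(s * gx / e_pred, _SOBEL_X)
        grad += _sobel_adjoint(s * gy / e_pred, _SOBEL_Y)
    return loss, grad


def one_cycle_lr(step: int, total_steps: int, max_lr: float,
                 pct_start: float = 0.3, div: float = 25.0,
                 final_div: float = 1e4) -> float:
    """Cosine one-cycle schedule: max_lr/div -> max_lr -> max_lr/final_div."""
    if not (0 <= step < total_steps):
        raise ValueError(f"step {step} outside [0, {total_steps})")
    warm = int(round(pct_start * (total_steps - 1)))
    lo0, lo1 = max_lr / div, max_lr / final_div
    if step <= warm:
        t = 1.0 if warm == 0 else step / warm
        return lo0 + (max_lr - lo0) * (1 - np.cos(np.pi * t)) / 2
    t = (step - warm) / (total_steps - 1 - warm)
    return lo1 + (max_lr - lo1) * (1 + np.cos(np.pi * t)) / 2


def _center_crop(img: GrayImage, crop: int) -> GrayImage:
    h, w = img.shape
    r0, c0 = (h - crop) // 2, (w - crop) // 2
    return GrayImage(img.pixels[r0:r0 + crop, c0:c0 + crop], img.spacing)


def train_stage(model: EDSR, labels: list[GrayImage], cfg: TrainConfig
                ) -> tuple[ModelBundle, MetricLog]:
    """Run one training stage; returns the best-validation checkpoint.

    Labels are split by image into train/validation (seeded); training
    pairs are generated inline per batch via random crop + k-space
    truncation.  Validation uses fixed centre crops so the tracked
    metrics are comparable across epochs.
    """
    from . import quality  # local import: quality is evaluation-only

    if not labels:
        raise ValueError("empty dataset")
    factor = model.cfg.scale
    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(len(labels))
    n_val = max(1, int(round(cfg.val_fraction * len(labels))))
    if len(labels) - n_val < 1:
        raise ValueError("dataset too small to split")
    val_labels = [labels[i] for i in order[:n_val]]
    train_labels = [labels[i] for i in order[n_val:]]

    val_pairs = []
    for lab in val_labels:
        hr = _center_crop(lab, cfg.label_crop)
        val_pairs.append((kspace_downsample(hr, factor), hr))

    steps_per_epoch = int(np.ceil(len(train_labels) / cfg.batch))
    total_steps = cfg.epochs * steps_per_epoch
    opt = Adam(model.parameters())
    log = MetricLog()
    best_loss, best_state, best_epoch = np.inf, None, -1
    step = 0
    for epoch in range(cfg.epochs):
        perm = rng.permutation(len(train_labels))
        train_losses = []
        for b in range(steps_per_epoch):
            idx = perm[b * cfg.batch:(b + 1) * cfg.batch]
            lrs, hrs = zip(*(make_pair(train_labels[i], cfg.label_crop, factor, rng)
                             for i in idx))
            x = np.stack([im.pixels for im in lrs])[:, None]
            y = np.stack([im.pixels for im in hrs])[:, None]
            pred = model.forward(x, train=True)
            losses, grads = zip(*(_edge_l1_loss_grad(pred[i, 0], y[i, 0],
                                                     cfg.edge_lambda)
                                  for i in range(len(idx))))
            loss = float(np.mean(losses))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}")
            dy = np.stack(grads)[:, None] / len(idx)
            model.zero_grad()
            model.backward(dy)
            lr = one_cycle_lr(step, total_steps, cfg.max_lr,
                              cfg.pct_start, cfg.div, cfg.final_div)
            opt.step(model.gradients(), lr)
            train_losses.append(loss)
            step += 1

        # validation pass
        v_edge, v_nrmse, v_ssim, v_psnr = [], [], [], []
        for lr_img, hr_img in val_pairs:
            pred = model.forward(lr_img.pixels[None, None], train=False)[0, 0]
            pred_img = GrayImage(np.maximum(pred, 0.0), hr_img.spacing)
            v_edge.append(edge_l1_loss(pred, hr_img.pixels, cfg.edge_lambda))
            v_nrmse.append(quality.nrmse(pred_img, hr_img))
            v_ssim.append(quality.ssim(pred_img, hr_img))
            v_psnr.append(quality.psnr(pred_img, hr_img))
        val_edge = float(np.mean(v_edge))
        log.append(epoch=epoch, train_loss=float(np.mean(train_losses)),
                   val_edge_l1=val_edge, val_nrmse=float(np.mean(v_nrmse)),
                   val_ssim=float(np.mean(v_ssim)), val_psnr=float(np.mean(v_psnr)))
        if val_edge < best_loss:
            best_loss = val_edge
            best_epoch = epoch
            best_state = {k: v.copy() for k, v in model.parameters().items()}

    assert best_state is not None
    bundle = ModelBundle(model.cfg, best_state, {
        "stage": cfg.stage, "seed": cfg.seed, "best_epoch": best_epoch,
        "val_edge_l1": best_loss,
    })
    return bundle, log
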