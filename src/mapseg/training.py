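"""One-class training on mixed normal + synthetic-lesion batches.

The network never sees a real lesion: batches mix polyp-free frames
(all-zero masks) with procedurally synthesized (image, mask) pairs.
The focal loss

    L = -alpha * (1 - p_t)**gamma * log(p_t),
    p_t = p if the pixel is lesion else 1 - p,

(alpha = 1, gamma = 4) concentrates the gradient on hard pixels, which
matters because lesions cover a small fraction of each frame. SGD with
momentum 0.9, weight decay 3e-4 and a cosine-annealed learning rate
starting at 0.01 drives the head; the encoder and memory bank stay
frozen, so per-image head inputs are computed once and cached. Model
selection keeps the checkpoint maximizing (IoU + Dice) / 2 on a
held-out validation split with its own fixed synthesis seeds.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from skimage.transform import resize

from .evaluation import evaluate_masks
from .memory_model import (
    ArchConfig,
    MapSegNet,
    MemoryBank,
    build_memory,
    head_inputs,
    stack_head_inputs,
)
from .nn import SGD
from .simpo import SimpoConfig, generate_sample


@dataclass
class TrainConfig:
    input_size: int = 256
    batch_size: int = 8
    epochs: int = 5000
    steps_per_epoch: int = 1
    lr0: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 0.0003
    focal_alpha: float = 1.0
    focal_gamma: float = 4.0
    val_fraction: float = 0.20
    synthetic_fraction: float = 0.5
    memory_samples: int = 30
    train_pool: int = 64  # synthetic training pairs kept in the cache
    val_pairs: int = 16  # held-out synthetic validation pairs
    eval_every: int = 1
    seed: int = 0
    arch: ArchConfig | None = None
    simpo: SimpoConfig | None = None

    def __post_init__(self):
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in (0, 1)")
        if not 0.0 <= self.synthetic_fraction <= 1.0:
            raise ValueError("synthetic_fraction must be in [0, 1]")
        if self.lr0 <= 0:
            raise ValueError("learning rate must be positive")


@dataclass
class Checkpoint:
    epoch: int
    val_iou: float
    val_dice: float
    model_state: dict
    bank: MemoryBank
    config: TrainConfig
    history: list = field(default_factory=list)

    @property
    def mean_score(self) -> float:
        return (self.val_iou + self.val_dice) / 2.0


class DivergenceError(RuntimeError):
    """Raised when the loss becomes non-finite."""


# -------------------------------------------------------------------- pieces

def focal_loss(pred: np.ndarray, target: np.ndarray, alpha: float = 1.0,
               gamma: float = 4.0, eps: float = 1e-7,
               return_grad: bool = False):
    """Mean pixel-wise focal loss; optionally also d(loss)/d(pred)."""
    p = np.clip(np.asarray(pred, dtype=np.float64), eps, 1.0 - eps)
    s = np.asarray(target) > 0
    if p.shape != s.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {s.shape}")
    pt = np.where(s, p, 1.0 - p)
    logpt = np.log(pt)
    loss = float(np.mean(-alpha * (1.0 - pt) ** gamma * logpt))
    if not return_grad:
        return loss
    # dL/dpt, then chain through pt = p or 1 - p
    if gamma == 0:
        dpt = -alpha / pt
    else:
        dpt = -alpha * (
            -gamma * (1.0 - pt) ** (gamma - 1.0) * logpt + (1.0 - pt) ** gamma / pt
        )
    grad = np.where(s, dpt, -dpt) / p.size
    # clipped pixels sit on a flat of the clamp; zero their gradient
    grad[(pred <= eps) | (pred >= 1.0 - eps)] = 0.0
    return loss, grad


def cosine_lr(epoch: int, total: int, lr0: float) -> float:
    """lr(e) = lr0 * (1 + cos(pi * e / total)) / 2."""
    if total <= 0:
        raise ValueError("total epochs must be positive")
    return lr0 * (1.0 + math.cos(math.pi * epoch / total)) / 2.0


def resize_pair(image: np.ndarray, mask: np.ndarray | None, size: int) -> tuple:
    """Bilinear image resize; nearest-neighbour mask binarization."""
    h, w = image.shape[:2]
    if (h, w) != (size, size):
        image = resize(image, (size, size), order=1, preserve_range=True,
                       anti_aliasing=True).astype(np.uint8)
        if mask is not None:
            mask = resize(mask.astype(float), (size, size), order=0,
                          preserve_range=True)
    if mask is None:
        mask = np.zeros((size, size))
    return image, (mask > 0.5).astype(np.uint8)


def make_batch(normals, synthetic, batch: int, synthetic_fraction: float,
               rng: np.random.Generator, size: int) -> tuple:
    """(images, masks) uint8 batch mixing synthetic pairs and normal
    frames with all-zero masks."""
    if batch < 2:
        raise ValueError("batch size must be >= 2")
    if len(normals) == 0 and synthetic_fraction < 1.0:
        raise ValueError("no normal images available")
    if len(synthetic) == 0 and synthetic_fraction > 0.0:
        raise ValueError("no synthetic samples available")
    n_syn = int(round(batch * synthetic_fraction))
    images, masks = [], []
    for _ in range(n_syn):
        s = synthetic[int(rng.integers(len(synthetic)))]
        img, m = resize_pair(s.image, s.mask, size)
        images.append(img)
        masks.append(m)
    for _ in range(batch - n_syn):
        img, m = resize_pair(normals[int(rng.integers(len(normals)))], None, size)
        images.append(img)
        masks.append(m)
    return np.stack(images), np.stack(masks)


# --------------------------------------------------------------------- train

def _cache_entry(image, mask, bank, encoder, size):
    img, m = resize_pair(image, mask, size)
    ci, attn = head_inputs(img, bank, encoder)
    return {"ci": ci, "attn": attn, "mask": m}


def _synthesize_pool(normals, templates, textures, count, seed, simpo_cfg):
    samples = []
    root = np.random.SeedSequence(seed)
    for i, child in enumerate(root.spawn(count)):
        img = normals[i % len(normals)]
        samples.append(
            generate_sample(img, templates, textures, np.random.default_rng(child), simpo_cfg)
        )
    return samples


def _forward_batch(model, entries, idxs, train_mode):
    ci_b, attn_b = stack_head_inputs(
        [(entries[i]["ci"], entries[i]["attn"]) for i in idxs]
    )
    model.train(train_mode)
    return model.forward_head(ci_b, attn_b)


def _validate(model, val_entries, batch):
    ious, dices = [], []
    from .nn.core import no_grad

    with no_grad():
        for lo in range(0, len(val_entries), batch):
            idxs = range(lo, min(lo + batch, len(val_entries)))
            prob = _forward_batch(model, val_entries, idxs, train_mode=False)
            for j, i in enumerate(idxs):
                pred = prob.data[j, 0] >= 0.5
                iou, dice = evaluate_masks(pred, val_entries[i]["mask"])
                ious.append(iou)
                dices.append(dice)
    return float(np.mean(ious)), float(np.mean(dices))


def train(config: TrainConfig, normals, templates, textures,
          log_path=None) -> Checkpoint:
    """Run the full loop on in-memory data; returns the best checkpoint.

    ``normals`` is a list of uint8 RGB frames; ``templates`` a mask
    template set; ``textures`` a list of texture images.
    """
    cfg = config
    simpo_cfg = cfg.simpo or SimpoConfig()
    rng = np.random.default_rng(cfg.seed)

    n_val = max(1, int(round(cfg.val_fraction * len(normals))))
    order = rng.permutation(len(normals))
    val_idx, train_idx = order[:n_val], order[n_val:]
    train_normals = [normals[i] for i in train_idx]
    val_normals = [normals[i] for i in val_idx]
    if not train_normals:
        raise ValueError("no training normals left after the validation split")

    arch = cfg.arch or ArchConfig(
        input_size=cfg.input_size, memory_samples=cfg.memory_samples, seed=cfg.seed
    )
    model = MapSegNet(arch)
    size = cfg.input_size
    bank_sources = [resize_pair(im, None, size)[0] for im in train_normals]
    bank = build_memory(bank_sources, min(cfg.memory_samples, len(bank_sources)),
                        cfg.seed, model.encoder)

    # fixed synthetic pools; validation seeds are disjoint from training's
    train_pool = _synthesize_pool(train_normals, templates, textures,
                                  cfg.train_pool, cfg.seed * 2 + 1, simpo_cfg)
    val_pool = _synthesize_pool(val_normals, templates, textures,
                                cfg.val_pairs, cfg.seed * 2 + 2, simpo_cfg)

    train_entries = [
        _cache_entry(s.image, s.mask, bank, model.encoder, size) for s in train_pool
    ] + [_cache_entry(im, None, bank, model.encoder, size) for im in train_normals]
    n_syn_entries = len(train_pool)
    val_entries = [
        _cache_entry(s.image, s.mask, bank, model.encoder, size) for s in val_pool
    ]

    opt = SGD(model.parameters(), lr=cfg.lr0, momentum=cfg.momentum,
              weight_decay=cfg.weight_decay)
    batch_rng = np.random.default_rng(cfg.seed + 17)
    best: Checkpoint | None = None
    history = []
    log_fh = open(log_path, "w") if log_path else None

    try:
        for epoch in range(cfg.epochs):
            lr = cosine_lr(epoch, cfg.epochs, cfg.lr0)
            opt.lr = lr
            epoch_losses = []
            for _ in range(cfg.steps_per_epoch):
                n_syn = int(round(cfg.batch_size * cfg.synthetic_fraction))
                syn_pick = batch_rng.integers(0, n_syn_entries, size=n_syn)
                norm_pick = batch_rng.integers(
                    n_syn_entries, len(train_entries), size=cfg.batch_size - n_syn
                )
                idxs = np.concatenate([syn_pick, norm_pick])
                masks = np.stack([train_entries[i]["mask"] for i in idxs])
                prob = _forward_batch(model, train_entries, idxs, train_mode=True)
                loss, grad = focal_loss(
                    prob.data[:, 0], masks, cfg.focal_alpha, cfg.focal_gamma,
                    return_grad=True,
                )
                if not np.isfinite(loss):
                    raise DivergenceError(f"non-finite loss at epoch {epoch}")
                opt.zero_grad()
                prob.backward(grad[:, None].astype(prob.data.dtype))
                opt.step()
                epoch_losses.append(loss)

            record = {"epoch": epoch, "lr": lr, "loss": float(np.mean(epoch_losses))}
            if epoch % cfg.eval_every == 0 or epoch == cfg.epochs - 1:
                val_iou, val_dice = _validate(model, val_entries, cfg.batch_size)
                record.update(val_iou=val_iou, val_dice=val_dice,
                              mean_score=(val_iou + val_dice) / 2)
                if best is None or record["mean_score"] > best.mean_score:
                    best = Checkpoint(
                        epoch=epoch, val_iou=val_iou, val_dice=val_dice,
                        model_state=model.state_dict(), bank=bank, config=cfg,
                    )
            history.append(record)
            if log_fh:
                log_fh.write(json.dumps(record) + "\n")
    finally:
        if log_fh:
            log_fh.close()

    assert best is not None
    best.history = history
    return best


def untrained_validation_score(config: TrainConfig, normals, templates, textures) -> dict:
    """Validation IoU/Dice of the freshly initialized model (epoch-0
    reference for learning checks); mirrors ``train``'s data plumbing."""
    cfg = replace(config, epochs=1, steps_per_epoch=1)
    simpo_cfg = cfg.simpo or SimpoConfig()
    rng = np.random.default_rng(cfg.seed)
    n_val = max(1, int(round(cfg.val_fraction * len(normals))))
    order = rng.permutation(len(normals))
    val_normals = [normals[i] for i in order[:n_val]]
    train_normals = [normals[i] for i in order[n_val:]]
    arch = cfg.arch or ArchConfig(
        input_size=cfg.input_size, memory_samples=cfg.memory_samples, seed=cfg.seed
    )
    model = MapSegNet(arch)
    size = cfg.input_size
    bank_sources = [resize_pair(im, None, size)[0] for im in train_normals]
    bank = build_memory(bank_sources, min(cfg.memory_samples, len(bank_sources)),
                        cfg.seed, model.encoder)
    val_pool = _synthesize_pool(val_normals, templates, textures,
                                cfg.val_pairs, cfg.seed * 2 + 2, simpo_cfg)
    val_entries = [
        _cache_entry(s.image, s.mask, bank, model.encoder, size) for s in val_pool
    ]
    # BN running stats of an untrained head are the init values; use them
    iou, dice = _validate(model, val_entries, cfg.batch_size)
    return {"val_iou": iou, "val_dice": dice, "mean_score": (iou + dice) / 2}
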