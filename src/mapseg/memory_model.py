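"""Memory-augmented encoder-decoder for anomaly segmentation.

The network models healthy mucosa with a fixed bank of multi-scale
feature prototypes extracted by a frozen ResNet18 trunk. For an input
image, per-scale squared-difference maps against the closest prototype
(minimum total discrepancy) localize deviations from normality; the
difference maps are concatenated with the input features, fused by a
multi-scale feature-fusion module with coordinate attention, modulated
by cascaded spatial-attention maps, and decoded with progressive x2
upsampling into a per-pixel anomaly probability.

All tensors are numpy float32; see :mod:`mapseg.nn` for the engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import functional as F
from .nn.core import Tensor, no_grad
from .nn.resnet import ResNet18Trunk

IMAGENET_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float32)
IMAGENET_STD = np.array([0.229, 0.224, 0.225], dtype=np.float32)


# --------------------------------------------------------------------- types

@dataclass
class FeaturePyramid:
    """Per-image encoder activations at three scales (C, H, W)."""

    f1: np.ndarray  # 64 channels,  1/4 resolution
    f2: np.ndarray  # 128 channels, 1/8 resolution
    f3: np.ndarray  # 256 channels, 1/16 resolution

    def scales(self):
        return (self.f1, self.f2, self.f3)


@dataclass
class MemoryBank:
    """Frozen per-scale feature prototypes of N normal images."""

    m1: np.ndarray  # (N, 64, H1, W1)
    m2: np.ndarray
    m3: np.ndarray
    indices: np.ndarray  # which normal images were selected

    @property
    def n(self) -> int:
        return self.m1.shape[0]

    def scales(self):
        return (self.m1, self.m2, self.m3)


@dataclass
class DifferenceMaps:
    """Selected squared-difference maps and their bank indices."""

    di_star: tuple  # three (C, H, W) arrays
    selected: tuple  # argmin bank index per scale
    total: tuple  # the minimal total sums per scale


@dataclass
class AttentionMaps:
    m1: np.ndarray  # finest
    m2: np.ndarray
    m3: np.ndarray  # coarsest


@dataclass
class ArchConfig:
    """Reference architecture; widths reproduce the published model size."""

    msffm_widths: tuple = (64, 128, 256)
    ca_reduction: int = 16
    bottleneck_width: int = 480
    bottleneck_blocks: int = 6
    decoder_widths: tuple = (144, 48, 32, 16)
    input_size: int = 256
    memory_samples: int = 30
    seed: int = 0

    def to_dict(self):
        return {
            "msffm_widths": list(self.msffm_widths),
            "ca_reduction": self.ca_reduction,
            "bottleneck_width": self.bottleneck_width,
            "bottleneck_blocks": self.bottleneck_blocks,
            "decoder_widths": list(self.decoder_widths),
            "input_size": self.input_size,
            "memory_samples": self.memory_samples,
            "seed": self.seed,
        }


# ---------------------------------------------------------------- preprocess

def preprocess(image: np.ndarray) -> np.ndarray:
    """uint8 RGB (H, W, 3) -> normalized float32 (3, H, W)."""
    x = image.astype(np.float32) / 255.0
    x = (x - IMAGENET_MEAN) / IMAGENET_STD
    return np.ascontiguousarray(x.transpose(2, 0, 1))


# ------------------------------------------------------------------- modules

def _conv_bn_relu(cin, cout, k, rng):
    return nn.Sequential(nn.Conv2d(cin, cout, k, rng=rng), nn.BatchNorm2d(cout), nn.ReLU())


class MSFFM(nn.Module):
    """Multi-scale feature fusion: per-scale 3x3 conv + coordinate
    attention, then coarse-to-fine additive alignment."""

    def __init__(self, in_chans=(128, 256, 512), widths=(64, 128, 256), reduction=16, rng=None):
        super().__init__()
        w1, w2, w3 = widths
        self.branch1 = _conv_bn_relu(in_chans[0], w1, 3, rng)
        self.branch2 = _conv_bn_relu(in_chans[1], w2, 3, rng)
        self.branch3 = _conv_bn_relu(in_chans[2], w3, 3, rng)
        self.ca1 = nn.CoordinateAttention(w1, reduction, rng=rng)
        self.ca2 = nn.CoordinateAttention(w2, reduction, rng=rng)
        self.ca3 = nn.CoordinateAttention(w3, reduction, rng=rng)
        self.up = nn.Upsample2x()
        self.align32 = nn.Sequential(nn.Conv2d(w3, w2, 1, pad=0, rng=rng), nn.BatchNorm2d(w2))
        self.align21 = nn.Sequential(nn.Conv2d(w2, w1, 1, pad=0, rng=rng), nn.BatchNorm2d(w1))

    def forward(self, ci1, ci2, ci3):
        g1 = self.ca1(self.branch1(ci1))
        g2 = self.ca2(self.branch2(ci2))
        g3 = self.ca3(self.branch3(ci3))
        g2 = F.relu(F.add(g2, self.align32(self.up(g3))))
        g1 = F.relu(F.add(g1, self.align21(self.up(g2))))
        return g1, g2, g3


class Decoder(nn.Module):
    """Progressive-upsampling decoder (1/16 -> full resolution)."""

    def __init__(self, widths=(64, 128, 256), d0=480, blocks=6, dec=(144, 48, 32, 16), rng=None):
        super().__init__()
        w1, w2, w3 = widths
        u32, u64, u128, u256 = dec
        self.entry = _conv_bn_relu(w3, d0, 3, rng)
        self.blocks = [_conv_bn_relu(d0, d0, 3, rng) for _ in range(blocks)]
        self.up = nn.Upsample2x()
        self.dec32a = _conv_bn_relu(d0 + w2, u32, 3, rng)
        self.dec32b = _conv_bn_relu(u32, u32, 3, rng)
        self.dec64a = _conv_bn_relu(u32 + w1, u64, 3, rng)
        self.dec64b = _conv_bn_relu(u64, u64, 3, rng)
        self.dec128 = _conv_bn_relu(u64, u128, 3, rng)
        self.dec256 = _conv_bn_relu(u128, u256, 3, rng)
        self.out = nn.Conv2d(u256, 1, 1, pad=0, bias=True, rng=rng)

    def forward(self, g1, g2, g3):
        x = self.entry(g3)
        for b in self.blocks:
            x = b(x)
        x = F.concat([self.up(x), g2], axis=1)
        x = self.dec32b(self.dec32a(x))
        x = F.concat([self.up(x), g1], axis=1)
        x = self.dec64b(self.dec64a(x))
        x = self.dec128(self.up(x))
        x = self.dec256(self.up(x))
        return F.sigmoid(self.out(x))


class MapSegNet(nn.Module):
    """Frozen encoder + trainable fusion/attention/decoder head."""

    def __init__(self, config: ArchConfig | None = None):
        super().__init__()
        self.config = config or ArchConfig()
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        self.encoder = ResNet18Trunk(seed=cfg.seed)
        self.msffm = MSFFM(
            in_chans=(128, 256, 512),
            widths=cfg.msffm_widths,
            reduction=cfg.ca_reduction,
            rng=rng,
        )
        self.decoder = Decoder(
            widths=cfg.msffm_widths,
            d0=cfg.bottleneck_width,
            blocks=cfg.bottleneck_blocks,
            dec=cfg.decoder_widths,
            rng=rng,
        )

    def train(self, mode=True):
        super().train(mode)
        self.encoder.train(False)  # frozen encoder stays in eval mode
        return self

    # -- head path (inputs are constants w.r.t. the gradient) --------------

    def forward_head(self, ci, attn):
        """ci: three (B, 2C, H, W) arrays; attn: three (B, 1, H, W) arrays
        ordered finest-to-coarsest. Returns the probability Tensor."""
        ci1, ci2, ci3 = (Tensor(c) for c in ci)
        a1, a2, a3 = (Tensor(a) for a in attn)
        g1, g2, g3 = self.msffm(ci1, ci2, ci3)
        g1 = F.mul(g1, a1)
        g2 = F.mul(g2, a2)
        g3 = F.mul(g3, a3)
        return self.decoder(g1, g2, g3)

    def forward(self, images: np.ndarray, bank: MemoryBank) -> np.ndarray:
        """Full forward pass for a (B, H, W, 3) uint8 batch -> (B, H, W)
        probabilities at the model resolution."""
        per_image = [head_inputs(img, bank, self.encoder) for img in images]
        ci_b, attn_b = stack_head_inputs(per_image)
        with no_grad():
            prob = self.forward_head(ci_b, attn_b)
        return prob.data[:, 0]


# ----------------------------------------------------------------- operations

def extract_features(image: np.ndarray, encoder: ResNet18Trunk) -> FeaturePyramid:
    """Encode one uint8 RGB image into its three-scale feature pyramid.

    The image side must be a multiple of 32 and at least 64 px so all
    three scales are well defined.
    """
    h, w = image.shape[:2]
    if h < 64 or w < 64 or h % 32 or w % 32:
        raise ValueError(f"input size {h}x{w} must be >=64 and a multiple of 32")
    x = preprocess(image)[None]
    f1, f2, f3 = encoder(x)
    return FeaturePyramid(f1[0], f2[0], f3[0])


def build_memory(
    normals, n: int, seed: int, encoder: ResNet18Trunk
) -> MemoryBank:
    """Select ``n`` normal images without replacement and freeze their
    feature pyramids as the prototype bank."""
    normals = list(normals)
    if n > len(normals):
        raise ValueError(f"requested {n} memory samples from {len(normals)} normals")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(normals), size=n, replace=False)
    pyramids = [extract_features(normals[i], encoder) for i in idx]
    return MemoryBank(
        m1=np.stack([p.f1 for p in pyramids]),
        m2=np.stack([p.f2 for p in pyramids]),
        m3=np.stack([p.f3 for p in pyramids]),
        indices=np.asarray(idx),
    )


def best_difference_map(pyr: FeaturePyramid, bank: MemoryBank) -> DifferenceMaps:
    """Per scale, the channel-preserving squared-difference map against
    the bank item with the minimum total pixel-wise discrepancy."""
    di_star, selected, totals = [], [], []
    for feat, mem in zip(pyr.scales(), bank.scales()):
        if feat.shape != mem.shape[1:]:
            raise ValueError(
                f"feature shape {feat.shape} does not match bank {mem.shape[1:]}"
            )
        diffs = (mem - feat[None]) ** 2  # (N, C, H, W)
        sums = diffs.reshape(bank.n, -1).sum(axis=1)
        k = int(np.argmin(sums))
        di_star.append(diffs[k])
        selected.append(k)
        totals.append(float(sums[k]))
    return DifferenceMaps(di_star=tuple(di_star), selected=tuple(selected), total=tuple(totals))


def spatial_attention(diff: DifferenceMaps) -> AttentionMaps:
    """Cascaded channel-mean attention: coarse maps gate finer ones
    multiplicatively after bilinear x2 upsampling."""
    d1, d2, d3 = diff.di_star
    m3 = d3.mean(axis=0)
    m2 = d2.mean(axis=0) * _up2(m3)
    m1 = d1.mean(axis=0) * _up2(m2)
    return AttentionMaps(m1=m1, m2=m2, m3=m3)


def _up2(m: np.ndarray) -> np.ndarray:
    h, w = m.shape
    ah = F.bilinear_matrix(h, 2 * h)
    aw = F.bilinear_matrix(w, 2 * w)
    return ah @ m @ aw.T


def head_inputs(image: np.ndarray, bank: MemoryBank, encoder) -> tuple:
    """Constant (w.r.t. the gradient) head inputs for one image:
    three concatenated feature/difference tensors and three attention
    maps, finest-to-coarsest. Cacheable because the encoder and bank
    are frozen."""
    pyr = extract_features(image, encoder)
    diff = best_difference_map(pyr, bank)
    att = spatial_attention(diff)
    ci = [np.concatenate([f, d], axis=0) for f, d in zip(pyr.scales(), diff.di_star)]
    attn = [att.m1[None], att.m2[None], att.m3[None]]
    return ci, attn


def stack_head_inputs(per_image) -> tuple:
    """Batch a list of ``head_inputs`` results into stacked arrays."""
    ci_b = [np.stack([ci[i] for ci, _ in per_image]) for i in range(3)]
    attn_b = [np.stack([attn[i] for _, attn in per_image]) for i in range(3)]
    return ci_b, attn_b


def count_parameters(model: MapSegNet) -> tuple[int, int]:
    """(total, trainable) parameter element counts."""
    total = trainable = 0
    for p in model.parameters():
        total += p.data.size
        if p.trainable:
            trainable += p.data.size
    return total, trainable


# ---------------------------------------------------------------- checkpoint

def save_checkpoint(path, model: MapSegNet, bank: MemoryBank | None, extra=None):
    payload = {f"model/{k}": v for k, v in model.state_dict().items()}
    if bank is not None:
        payload["bank/m1"] = bank.m1
        payload["bank/m2"] = bank.m2
        payload["bank/m3"] = bank.m3
        payload["bank/indices"] = bank.indices
    payload["config/json"] = np.frombuffer(
        repr(model.config.to_dict()).encode(), dtype=np.uint8
    )
    if extra:
        for k, v in extra.items():
            payload[f"extra/{k}"] = np.asarray(v)
    np.savez_compressed(path, **payload)


def load_checkpoint(path):
    import ast

    with np.load(path) as z:
        cfg = ArchConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in ast.literal_eval(bytes(z["config/json"]).decode()).items()
        })
        model = MapSegNet(cfg)
        model.load_state_dict(
            {k[len("model/"):]: z[k] for k in z.files if k.startswith("model/")}
        )
        bank = None
        if "bank/m1" in z.files:
            bank = MemoryBank(
                m1=z["bank/m1"], m2=z["bank/m2"], m3=z["bank/m3"], indices=z["bank/indices"]
            )
        extra = {
            k[len("extra/"):]: z[k] for k in z.files if k.startswith("extra/")
        }
    return model, bank, extra
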