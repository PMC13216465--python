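"""SIMPO: procedural synthesis of polyp-like lesions in normal frames.

A placed lesion mask is filled with one of three content strategies,
mirroring the NICE appearance classes of colorectal polyps:

* ``patch``  - the frame itself, photometrically and geometrically
  perturbed (pale, low-contrast lesions);
* ``texture`` - an external texture recolored to the frame's color
  distribution (dark, amorphous lesions);
* ``hybrid``  - a convex combination of the two,
  ``O = I (+) M . [(1 - alpha) I' + alpha Tc']`` with
  ``alpha ~ U(0.3, 0.7)`` (brownish, mixed-texture lesions).

Modes are drawn with probabilities 40/40/20. Blending adds a soft
shadow from the Gaussian-blurred mask; pixels with zero blurred-mask
weight are bit-identical to the source frame.

Reproducibility: every operation consumes dedicated child streams
spawned in a fixed slot order from the caller's generator, so the
hybrid limits (alpha -> 0 or 1) are bitwise equal to the pure modes
under shared seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.color import hsv2rgb, rgb2hsv
from skimage.transform import AffineTransform, rotate, warp

from .color_transfer import iterative_distribution_transfer, texture_restoration
from .mask_gen import (
    MaskTemplateSet,
    PolypMask,
    compute_valid_region,
    place_mask,
    transform_mask,
)

MODES = ("patch", "texture", "hybrid")
MODE_WEIGHTS = (0.4, 0.4, 0.2)

# spawn-slot layout shared by all synthesis ops (bitwise-equal limits)
_SLOT_PATCH, _SLOT_IDT, _SLOT_TEXTURE, _SLOT_ALPHA = 0, 1, 2, 3


@dataclass
class TransformOp:
    name: str
    rng_range: tuple  # (lo, hi); ignored for flips
    probability: float


def default_transform_rows() -> list:
    """Geometric and colorimetric perturbations, in application order."""
    return [
        TransformOp("hflip", (0, 0), 0.5),
        TransformOp("vflip", (0, 0), 0.5),
        TransformOp("rotation", (-90.0, 90.0), 1.0),
        TransformOp("xscale", (0.65, 1.0), 0.5),
        TransformOp("multiply", (1.5, 2.0), 1.0),
        TransformOp("gamma", (0.5, 1.5), 1.0),
        TransformOp("blur", (5.0, 5.0), 0.5),
        TransformOp("huesat", (-10.0, 10.0), 0.5),
    ]


@dataclass
class SimpoConfig:
    mode_weights: tuple = MODE_WEIGHTS
    rows: list = field(default_factory=default_transform_rows)
    shadow_sigma: float = 7.0
    shadow_strength: float = 0.3
    alpha_range: tuple = (0.3, 0.7)
    idt_iterations: int = 10

    def with_disabled_transforms(self) -> "SimpoConfig":
        rows = [replace(r, probability=0.0) for r in self.rows]
        return replace(self, rows=rows)


@dataclass
class SyntheticSample:
    image: np.ndarray  # uint8 RGB, lesion composited
    mask: np.ndarray  # {0,1} ground truth
    mode: str
    meta: dict = field(default_factory=dict)


# ------------------------------------------------------------------ sampling

def select_mode(rng: np.random.Generator, weights=None) -> str:
    w = np.asarray(weights if weights is not None else MODE_WEIGHTS, dtype=float)
    if w.sum() <= 0:
        raise ValueError("mode weights must sum to a positive value")
    return str(rng.choice(MODES, p=w / w.sum()))


# ---------------------------------------------------------------- transforms

def _apply_row(img: np.ndarray, row: TransformOp, apply: bool, param: float) -> np.ndarray:
    """img float64 in [0, 255]; returns same range un-clipped."""
    if not apply:
        return img
    if row.name == "hflip":
        return img[:, ::-1]
    if row.name == "vflip":
        return img[::-1]
    if row.name == "rotation":
        return rotate(img / 255.0, param, mode="reflect", order=1) * 255.0
    if row.name == "xscale":
        h, w = img.shape[:2]
        t = (
            AffineTransform(translation=(-w / 2, -h / 2))
            + AffineTransform(scale=(param, 1.0))
            + AffineTransform(translation=(w / 2, h / 2))
        )
        return warp(img / 255.0, t.inverse, mode="reflect", order=1) * 255.0
    if row.name == "multiply":
        return img * param
    if row.name == "gamma":
        return np.power(np.clip(img, 0, 255) / 255.0, param) * 255.0
    if row.name == "blur":
        return np.stack(
            [gaussian_filter(img[..., c], row.rng_range[0]) for c in range(3)], axis=-1
        )
    if row.name == "huesat":
        hsv = rgb2hsv(np.clip(img, 0, 255) / 255.0)
        hsv[..., 0] = (hsv[..., 0] + param / 360.0) % 1.0
        hsv[..., 1] = np.clip(hsv[..., 1] + param / 255.0, 0.0, 1.0)
        return hsv2rgb(hsv) * 255.0
    raise ValueError(f"unknown transform row {row.name!r}")


def photometric_geometric_transform(
    img: np.ndarray, rng: np.random.Generator, config: SimpoConfig | None = None
) -> np.ndarray:
    """Apply the configured perturbation rows in order; each row fires
    with its probability and a parameter uniform in its range."""
    config = config or SimpoConfig()
    out = img.astype(np.float64)
    for row in config.rows:
        gate = rng.uniform() < row.probability
        param = rng.uniform(*row.rng_range)
        out = _apply_row(out, row, gate, param)
    return np.clip(out + 0.5, 0, 255).astype(np.uint8)


# ------------------------------------------------------------------ blending

def shadow_blend(
    base: np.ndarray,
    content: np.ndarray,
    mask: PolypMask | np.ndarray,
    config: SimpoConfig | None = None,
) -> np.ndarray:
    """Composite content into base through the mask with a soft,
    contour-focused shadow.

    The blurred mask B (Gaussian, sigma = ``shadow_sigma``, normalized
    to max 1) darkens the base by ``1 - strength*B`` and feathers the
    content at the rim; where B is exactly zero the output bytes equal
    the base bytes.
    """
    config = config or SimpoConfig()
    m = (mask.grid if isinstance(mask, PolypMask) else np.asarray(mask)) > 0
    if m.shape != base.shape[:2] or content.shape != base.shape:
        raise ValueError("shape mismatch between base, content and mask")
    b = gaussian_filter(m.astype(np.float64), config.shadow_sigma, truncate=3.0)
    peak = b.max()
    if peak > 0:
        b = b / peak
    out = base.astype(np.float64) * (1.0 - config.shadow_strength * b[..., None])
    w = (m * b)[..., None]
    out = out * (1.0 - w) + content.astype(np.float64) * w
    out = np.clip(out + 0.5, 0, 255).astype(np.uint8)
    untouched = b == 0
    out[untouched] = base[untouched]
    return out


# ----------------------------------------------------------------- synthesis

def patch_synthesis(
    image: np.ndarray, mask: PolypMask, rng: np.random.Generator,
    config: SimpoConfig | None = None,
) -> SyntheticSample:
    """Lesion content is the (transformed) frame itself."""
    config = config or SimpoConfig()
    children = rng.spawn(1)
    transformed = photometric_geometric_transform(image, children[_SLOT_PATCH], config)
    out = shadow_blend(image, transformed, mask, config)
    return SyntheticSample(image=out, mask=mask.grid.copy(), mode="patch")


def fit_texture(texture: np.ndarray, shape: tuple) -> np.ndarray:
    """Tile then center-crop a texture to the target (H, W)."""
    h, w = shape[:2]
    th, tw = texture.shape[:2]
    reps = (int(np.ceil(h / th)), int(np.ceil(w / tw)), 1)
    tiled = np.tile(texture, reps)
    y0 = (tiled.shape[0] - h) // 2
    x0 = (tiled.shape[1] - w) // 2
    return tiled[y0 : y0 + h, x0 : x0 + w]


def _recolored_texture(image, texture, idt_rng, config):
    seed = int(idt_rng.integers(2**31))
    fitted = fit_texture(texture, image.shape)
    recolored = iterative_distribution_transfer(
        fitted, image, n_iter=config.idt_iterations, seed=seed
    )
    return texture_restoration(fitted, recolored)


def texture_synthesis(
    image: np.ndarray, texture: np.ndarray, mask: PolypMask, rng: np.random.Generator,
    config: SimpoConfig | None = None,
) -> SyntheticSample:
    """Lesion content is an external texture, recolored to the frame."""
    config = config or SimpoConfig()
    children = rng.spawn(3)
    tc = _recolored_texture(image, texture, children[_SLOT_IDT], config)
    tc_t = photometric_geometric_transform(tc, children[_SLOT_TEXTURE], config)
    out = shadow_blend(image, tc_t, mask, config)
    return SyntheticSample(image=out, mask=mask.grid.copy(), mode="texture")


def hybrid_synthesis(
    image: np.ndarray, texture: np.ndarray, mask: PolypMask, rng: np.random.Generator,
    config: SimpoConfig | None = None, alpha: float | None = None,
) -> SyntheticSample:
    """Convex combination of patch and texture content inside the mask."""
    config = config or SimpoConfig()
    children = rng.spawn(4)
    patch_c = photometric_geometric_transform(image, children[_SLOT_PATCH], config)
    tc = _recolored_texture(image, texture, children[_SLOT_IDT], config)
    tex_c = photometric_geometric_transform(tc, children[_SLOT_TEXTURE], config)
    if alpha is None:
        alpha = float(children[_SLOT_ALPHA].uniform(*config.alpha_range))
    if alpha == 0.0:
        content = patch_c
    elif alpha == 1.0:
        content = tex_c
    else:
        content = np.clip(
            (1.0 - alpha) * patch_c.astype(np.float64)
            + alpha * tex_c.astype(np.float64)
            + 0.5,
            0,
            255,
        ).astype(np.uint8)
    out = shadow_blend(image, content, mask, config)
    return SyntheticSample(
        image=out, mask=mask.grid.copy(), mode="hybrid", meta={"alpha": alpha}
    )


# --------------------------------------------------------------- entry point

def generate_sample(
    image: np.ndarray,
    templates: MaskTemplateSet,
    textures,
    rng: np.random.Generator,
    config: SimpoConfig | None = None,
) -> SyntheticSample:
    """Full pipeline: sample and transform a template mask, constrain
    it to the valid mucosal region, pick a synthesis mode, composite."""
    config = config or SimpoConfig()
    if len(templates) == 0 or len(textures) == 0:
        raise ValueError("need non-empty template and texture pools")
    c_mask, c_place, c_mode, c_synth = rng.spawn(4)
    idx = int(c_mask.integers(len(templates)))
    mt = transform_mask(templates[idx], c_mask, target_size=image.shape[0])
    mo = compute_valid_region(image)
    placed = place_mask(mt, mo, rng=c_place)
    mode = select_mode(c_mode, config.mode_weights)
    tex = textures[int(c_mode.integers(len(textures)))]
    if mode == "patch":
        sample = patch_synthesis(image, placed, c_synth, config)
    elif mode == "texture":
        sample = texture_synthesis(image, tex, placed, c_synth, config)
    else:
        sample = hybrid_synthesis(image, tex, placed, c_synth, config)
    sample.meta.update({"template_index": idx, "mode": mode})
    return sample
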