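"""Seeded procedural stand-ins for endoscopy data.

Two generators make the whole pipeline testable offline:

* :func:`generate_mucosa` - reddish-pink, low-frequency "healthy mucosa"
  images with optional vignette, specular highlights and a corner
  thumbnail (emulating the acquisition bias of a well-known public
  endoscopy corpus, where normal frames carry a green position
  thumbnail in the lower-left corner).
* :func:`generate_texture` - noise-based color textures standing in for
  external texture photographs used by the texture synthesis mode.

Everything is a pure function of its spec (seed included).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage
from skimage.color import hsv2rgb

from .io import imwrite

#: geometry of the corner thumbnail: 40x40 px, lower-left, 8 px inset
THUMBNAIL_SIZE = 40
THUMBNAIL_OFFSET = 8


@dataclass
class MucosaSpec:
    size: int = 512
    base_hue: float = 355.0  # degrees; wraps through red ([330, 25])
    noise_octaves: int = 4
    vignette_strength: float = 0.5
    specular_count: int = 3
    thumbnail: str = "none"  # none | green | black
    seed: int = 0

    def validate(self):
        if self.size < 64:
            raise ValueError("mucosa size must be >= 64 (three encoder scales)")
        if self.noise_octaves < 1:
            raise ValueError("noise_octaves must be >= 1")
        if not 0.0 <= self.vignette_strength <= 1.0:
            raise ValueError("vignette_strength must be in [0, 1]")
        if self.specular_count < 0:
            raise ValueError("specular_count must be >= 0")
        if self.thumbnail not in ("none", "green", "black"):
            raise ValueError(f"unknown thumbnail option {self.thumbnail!r}")


@dataclass
class TextureSpec:
    size: int = 512
    palette: tuple = ((92, 61, 36), (156, 112, 74), (61, 38, 23))
    granularity: float = 16.0  # pixels per noise cell
    seed: int = 0

    def validate(self):
        if len(self.palette) == 0:
            raise ValueError("texture palette must contain at least one anchor")
        if self.granularity <= 0:
            raise ValueError("granularity must be positive")


def value_noise(rng, size: int, octaves: int, base_cells: int = 4) -> np.ndarray:
    """Multi-octave value noise in [-1, 1]; per-octave amplitude halving."""
    acc = np.zeros((size, size), dtype=np.float64)
    amp, total = 1.0, 0.0
    for o in range(octaves):
        cells = base_cells * (2**o)
        grid = rng.uniform(-1.0, 1.0, size=(cells + 1, cells + 1))
        zoom = size / (cells + 1)
        layer = ndimage.zoom(grid, zoom, order=3, mode="reflect", grid_mode=True)
        acc += amp * layer[:size, :size]
        total += amp
        amp *= 0.5
    return acc / total


def generate_mucosa(spec: MucosaSpec) -> np.ndarray:
    """Render one mucosa-like uint8 RGB image from its spec."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    s = spec.size
    hue_noise = value_noise(rng, s, spec.noise_octaves)
    sat_noise = value_noise(rng, s, spec.noise_octaves)
    val_noise = value_noise(rng, s, max(1, spec.noise_octaves - 1))

    hue = (spec.base_hue + 10.0 * hue_noise) % 360.0
    sat = np.clip(0.45 + 0.18 * sat_noise, 0.15, 0.75)
    val = np.clip(0.62 + 0.22 * val_noise, 0.20, 0.92)

    if spec.vignette_strength > 0:
        yy, xx = np.mgrid[0:s, 0:s]
        r2 = ((yy - s / 2) ** 2 + (xx - s / 2) ** 2) / ((s / 2) ** 2)
        val *= 1.0 - spec.vignette_strength * 0.6 * np.clip(r2, 0, 1)

    hsv = np.stack([hue / 360.0, sat, val], axis=-1)
    img = hsv2rgb(hsv)

    for _ in range(spec.specular_count):
        cy, cx = rng.uniform(0.1 * s, 0.9 * s, size=2)
        radius = rng.uniform(0.004 * s, 0.012 * s)
        yy, xx = np.mgrid[0:s, 0:s]
        blob = np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * radius**2)))
        img = img + blob[..., None] * (1.05 - img)

    img = np.clip(img, 0, 1)
    out = (img * 255.0 + 0.5).astype(np.uint8)

    if spec.thumbnail != "none":
        color = (0, 170, 0) if spec.thumbnail == "green" else (0, 0, 0)
        y0 = s - THUMBNAIL_OFFSET - THUMBNAIL_SIZE
        x0 = THUMBNAIL_OFFSET
        out[y0 : y0 + THUMBNAIL_SIZE, x0 : x0 + THUMBNAIL_SIZE] = color
    return out


def generate_texture(spec: TextureSpec) -> np.ndarray:
    """Render one texture patch; raises if the result is degenerate
    (per-channel standard deviation below 5 gray levels)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    s = spec.size
    cells = max(2, int(round(s / spec.granularity)))
    octaves = 3
    field = value_noise(rng, s, octaves, base_cells=cells)
    t = (field - field.min()) / max(np.ptp(field), 1e-12)  # [0, 1]

    palette = np.asarray(spec.palette, dtype=np.float64)
    if len(palette) == 1:
        img = np.broadcast_to(palette[0], (s, s, 3)).copy()
    else:
        pos = t * (len(palette) - 1)
        lo = np.floor(pos).astype(int)
        hi = np.minimum(lo + 1, len(palette) - 1)
        frac = (pos - lo)[..., None]
        img = palette[lo] * (1 - frac) + palette[hi] * frac

    img = img + rng.normal(0.0, 3.0, size=img.shape)  # fine grain
    out = np.clip(img, 0, 255).astype(np.uint8)

    sds = out.reshape(-1, 3).std(axis=0)
    if (sds < 5.0).any():
        raise ValueError(f"degenerate texture: channel sd {sds} below 5")
    return out


def build_fixture_dataset(
    n_normal: int, n_textures: int, out_dir, seed: int = 0, overwrite: bool = False,
    size: int = 512,
) -> dict:
    """Write a seeded fixture dataset (PNGs + YAML manifest) to disk."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} is not empty (pass overwrite=True)")
    out.mkdir(parents=True, exist_ok=True)

    entries = []
    for i in range(n_normal):
        item_seed = seed * 100_003 + i
        spec = MucosaSpec(
            size=size,
            base_hue=float((340 + 3 * (i % 15)) % 360),
            vignette_strength=0.3 + 0.4 * ((i % 5) / 4),
            specular_count=i % 4,
            thumbnail="green" if i % 3 == 0 else "none",
            seed=item_seed,
        )
        name = f"normal_{i:04d}.png"
        imwrite(out / name, generate_mucosa(spec))
        entries.append({"filename": name, "kind": "normal", "seed": item_seed})

    brownish = [
        ((92, 61, 36), (156, 112, 74), (61, 38, 23)),
        ((40, 26, 18), (110, 74, 48), (20, 14, 10)),
        ((140, 96, 70), (200, 168, 130), (90, 60, 40)),
        ((70, 70, 60), (130, 120, 100), (50, 45, 40)),
    ]
    for i in range(n_textures):
        item_seed = seed * 100_003 + 50_000 + i
        spec = TextureSpec(
            size=size,
            palette=brownish[i % len(brownish)],
            granularity=8.0 + 6.0 * (i % 4),
            seed=item_seed,
        )
        name = f"texture_{i:04d}.png"
        imwrite(out / name, generate_texture(spec))
        entries.append({"filename": name, "kind": "texture", "seed": item_seed})

    manifest = {"seed": seed, "size": size, "entries": entries}
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest
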