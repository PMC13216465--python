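"""Iterative distribution transfer for texture recoloring.

Transfers the 3D color distribution of a reference image onto a texture
by repeatedly matching 1D marginals along rotated orthonormal axes
(Pitie-style sliced transport), then restores the texture's
high-frequency structure so that only its color statistics change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.stats import special_ortho_group


@dataclass
class ColorCloud:
    """A flat set of RGB samples plus the image shape to fold back to."""

    samples: np.ndarray  # (n, 3) float, 0..255 scale
    origin: tuple  # (height, width)

    @classmethod
    def from_image(cls, image: np.ndarray) -> "ColorCloud":
        h, w = image.shape[:2]
        return cls(samples=image.reshape(-1, 3).astype(np.float64), origin=(h, w))

    def to_image(self) -> np.ndarray:
        h, w = self.origin
        return self.samples.reshape(h, w, 3)


def match_cdf_1d(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Monotone map sending source quantiles onto target quantiles.

    Each source sample is replaced by the target quantile at its own
    rank, with linear interpolation between target order statistics.
    """
    source = np.asarray(source, dtype=np.float64).ravel()
    target = np.asarray(target, dtype=np.float64).ravel()
    if source.size == 0 or target.size == 0:
        raise ValueError("empty sample set")
    order = np.argsort(source, kind="stable")
    ranks = (np.arange(source.size) + 0.5) / source.size
    t_sorted = np.sort(target, kind="stable")
    t_ranks = (np.arange(target.size) + 0.5) / target.size
    mapped = np.interp(ranks, t_ranks, t_sorted)
    out = np.empty_like(source)
    out[order] = mapped
    return out


def idt_step(source: ColorCloud, target: ColorCloud, basis: np.ndarray) -> ColorCloud:
    """One sliced matching step along three orthonormal axes."""
    basis = np.asarray(basis, dtype=np.float64)
    if basis.shape != (3, 3) or not np.allclose(basis @ basis.T, np.eye(3), atol=1e-6):
        raise ValueError("basis must be a 3x3 orthonormal matrix")
    src_proj = source.samples @ basis.T  # rows of basis are the axes
    tgt_proj = target.samples @ basis.T
    matched = np.column_stack(
        [match_cdf_1d(src_proj[:, k], tgt_proj[:, k]) for k in range(3)]
    )
    new_samples = source.samples + (matched - src_proj) @ basis
    return ColorCloud(samples=new_samples, origin=source.origin)


def iterative_distribution_transfer(
    texture: np.ndarray, reference: np.ndarray, n_iter: int = 10, seed: int = 0
) -> np.ndarray:
    """Recolor ``texture`` toward ``reference``'s color distribution.

    The first iteration uses the identity (RGB) basis; later iterations
    use seeded random rotations. The output is clipped to [0, 255].
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    src = ColorCloud.from_image(texture)
    tgt = ColorCloud.from_image(reference)
    rng = np.random.default_rng(seed)
    for it in range(n_iter):
        basis = np.eye(3) if it == 0 else special_ortho_group.rvs(3, random_state=rng)
        src = idt_step(src, tgt, basis)
    out = np.clip(src.to_image(), 0.0, 255.0)
    return (out + 0.5).astype(np.uint8)


def texture_restoration(original: np.ndarray, recolored: np.ndarray, sigma: float = 2.0) -> np.ndarray:
    """Keep the recolored low frequencies, restore the original's
    high-frequency structure (per channel Gaussian split)."""
    if original.shape != recolored.shape:
        raise ValueError("shape mismatch between original and recolored")
    orig = original.astype(np.float64)
    reco = recolored.astype(np.float64)
    low_reco = np.stack(
        [gaussian_filter(reco[..., c], sigma) for c in range(3)], axis=-1
    )
    low_orig = np.stack(
        [gaussian_filter(orig[..., c], sigma) for c in range(3)], axis=-1
    )
    out = low_reco + (orig - low_orig)
    return np.clip(out + 0.5, 0, 255).astype(np.uint8)
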