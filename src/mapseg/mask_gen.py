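"""Polyp-shaped binary mask generation and placement.

Lesion contours are drawn in polar coordinates as a unit circle
perturbed by a sum of sinusoidal harmonics,

    r(theta) = 1 + sum_i  xi_i * omega_i * sin(i*theta + phi_i),

with quadratically decaying amplitudes ``omega_i = 1/i**2`` (Brownian
noise spectrum: smooth, organic outlines), random phases
``phi_i ~ U(0, 2*pi)`` and random per-harmonic scales
``xi_i ~ U(0, 1)``. A pre-generated template set of such masks is
sampled at training time; each sampled template is geometrically
transformed, then intersected with the anatomically valid region of the
target frame to give the final placement mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage
from scipy.interpolate import CubicSpline
from skimage.draw import polygon as draw_polygon
from skimage.filters import threshold_otsu
from skimage.measure import label
from skimage.morphology import opening as binary_opening
from skimage.transform import AffineTransform, warp

from .io import mask_read, mask_write


class DegenerateContourError(ValueError):
    """Raised when a sampled contour has a non-positive radius."""


class PlacementError(RuntimeError):
    """Raised when a mask cannot be placed inside the valid region."""


# --------------------------------------------------------------------- types

@dataclass
class ContourSpec:
    phases: np.ndarray  # phi_i in [0, 2*pi)
    scales: np.ndarray  # xi_i in [0, 1]

    def __post_init__(self):
        self.phases = np.asarray(self.phases, dtype=np.float64)
        self.scales = np.asarray(self.scales, dtype=np.float64)
        if self.phases.shape != self.scales.shape:
            raise ValueError("phases and scales must have equal length")
        if self.n < 1:
            raise ValueError("at least one harmonic required")

    @property
    def n(self) -> int:
        return len(self.phases)

    @property
    def amplitudes(self) -> np.ndarray:
        """omega_i = 1 / i**2 (computed, never stored)."""
        i = np.arange(1, self.n + 1, dtype=np.float64)
        return 1.0 / i**2


@dataclass
class PolypMask:
    grid: np.ndarray  # {0,1} uint8
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.grid = (np.asarray(self.grid) > 0).astype(np.uint8)

    @property
    def area(self) -> int:
        return int(self.grid.sum())


@dataclass
class MaskTemplateSet:
    masks: list  # of PolypMask
    seed: int

    def __len__(self):
        return len(self.masks)

    def __getitem__(self, i) -> PolypMask:
        return self.masks[i]


# ---------------------------------------------------------------- operations

def sample_contour(rng: np.random.Generator, n: int = 1000, shared_scale: bool = False) -> ContourSpec:
    """Draw a random contour spec: phases U(0, 2pi), scales U(0, 1).

    ``shared_scale`` uses one xi for all harmonics instead of
    independent per-harmonic draws (both interpretations are plausible
    readings of the shape model; per-harmonic is the default).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    phases = rng.uniform(0.0, 2 * np.pi, size=n)
    if shared_scale:
        scales = np.full(n, rng.uniform(0.0, 1.0))
    else:
        scales = rng.uniform(0.0, 1.0, size=n)
    return ContourSpec(phases=phases, scales=scales)


def evaluate_radius(spec: ContourSpec, theta) -> np.ndarray:
    """r(theta) = 1 + sum_i xi_i * omega_i * sin(i*theta + phi_i)."""
    theta = np.atleast_1d(np.asarray(theta, dtype=np.float64))
    i = np.arange(1, spec.n + 1, dtype=np.float64)
    coeff = spec.scales * spec.amplitudes
    # (T, n) phase matrix; fine for n=1000 and T ~ hundreds
    r = 1.0 + np.sin(np.outer(theta, i) + spec.phases) @ coeff
    return r


def rasterize_template(
    spec: ContourSpec,
    k_points: int = 50,
    upsample: int = 10,
    grid: int = 512,
    fill_fraction: float = 0.9,
) -> PolypMask:
    """Discretize, spline-smooth and fill one contour on a square grid.

    The contour is evaluated at ``k_points`` equally spaced angles,
    interpolated with a closed periodic cubic spline to
    ``k_points * upsample`` boundary points, rescaled (aspect
    preserved) so its larger bounding-box side spans
    ``fill_fraction * grid``, centered, and filled.
    """
    if k_points < 3:
        raise ValueError("need at least 3 contour points")
    theta = np.linspace(0.0, 2 * np.pi, k_points, endpoint=False)
    r = evaluate_radius(spec, theta)
    if r.min() <= 1e-3:
        raise DegenerateContourError("contour radius is non-positive; resample")
    x = r * np.cos(theta)
    y = r * np.sin(theta)
    pts = np.column_stack([x, y])
    closed = np.vstack([pts, pts[:1]])
    t = np.arange(k_points + 1, dtype=np.float64)
    spline = CubicSpline(t, closed, bc_type="periodic")
    dense = spline(np.linspace(0.0, k_points, k_points * upsample, endpoint=False))

    span = dense.max(axis=0) - dense.min(axis=0)
    scale = fill_fraction * grid / span.max()
    center = (dense.max(axis=0) + dense.min(axis=0)) / 2
    mapped = (dense - center) * scale + grid / 2.0

    rr, cc = draw_polygon(mapped[:, 1], mapped[:, 0], shape=(grid, grid))
    out = np.zeros((grid, grid), dtype=np.uint8)
    out[rr, cc] = 1
    if out.sum() == 0:
        raise DegenerateContourError("rasterized contour has no interior")
    return PolypMask(grid=out, provenance={"boundary_points": len(dense)})


def build_template_set(
    count: int = 1000, seed: int = 0, n_harmonics: int = 1000, grid: int = 512,
    shared_scale: bool = False,
) -> MaskTemplateSet:
    """Pre-generate the template mask dataset (fresh random contour per
    mask; degenerate draws are resampled)."""
    if count < 1:
        raise ValueError("count must be >= 1")
    rng = np.random.default_rng(seed)
    masks = []
    for idx in range(count):
        for _ in range(20):
            spec = sample_contour(rng, n_harmonics, shared_scale=shared_scale)
            try:
                m = rasterize_template(spec, grid=grid)
            except DegenerateContourError:
                continue
            m.provenance["template_index"] = idx
            masks.append(m)
            break
        else:  # pragma: no cover - vanishingly unlikely
            raise DegenerateContourError(f"could not sample template {idx}")
    return MaskTemplateSet(masks=masks, seed=seed)


def save_template_set(tset: MaskTemplateSet, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    names = []
    for i, m in enumerate(tset.masks):
        name = f"template_{i:04d}.png"
        mask_write(out / name, m.grid)
        names.append(name)
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump({"seed": tset.seed, "count": len(names), "masks": names}, fh)


def load_template_set(in_dir) -> MaskTemplateSet:
    src = Path(in_dir)
    with open(src / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    masks = [
        PolypMask(grid=mask_read(src / name), provenance={"template_index": i})
        for i, name in enumerate(manifest["masks"])
    ]
    return MaskTemplateSet(masks=masks, seed=manifest["seed"])


# ------------------------------------------------------------ transformation

def _warp_binary(mask: np.ndarray, tform: AffineTransform) -> np.ndarray:
    return warp(
        mask.astype(np.float64), tform.inverse, order=0, preserve_range=True
    ) > 0.5


def elastic_displacement(rng, size: int, control: int = 8, max_frac: float = 0.05):
    """Coarse random displacement field, cubic-upsampled to full size."""
    disp = rng.uniform(-1.0, 1.0, size=(2, control, control)) * max_frac * size
    field_full = np.stack(
        [
            ndimage.zoom(d, size / control, order=3, mode="reflect", grid_mode=True)[
                :size, :size
            ]
            for d in disp
        ]
    )
    return field_full


def _apply_elastic(mask: np.ndarray, field_full: np.ndarray) -> np.ndarray:
    size = mask.shape[0]
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    coords = np.stack([yy + field_full[0], xx + field_full[1]])
    return ndimage.map_coordinates(mask.astype(np.float64), coords, order=0) > 0.5


def transform_mask(
    template: PolypMask,
    rng: np.random.Generator,
    target_size: int = 512,
    identity: bool = False,
    scale: float | None = None,
    elastic: bool = True,
    downscale: float = 0.6,
    scale_range: tuple = (0.2, 0.9),
    max_attempts: int = 10,
) -> PolypMask:
    """Randomly transform a template: downscale to 60% of its extent,
    rotate, translate (staying in frame), elastically deform, then apply
    a global scale drawn from U(0.2, 0.9), and resample onto the target
    grid. ``identity=True`` only resamples (exposed for tests)."""
    src = template.grid
    size = src.shape[0]
    if identity:
        out = _resample(src, target_size)
        return PolypMask(grid=out, provenance={**template.provenance, "identity": True})

    for _ in range(max_attempts):
        angle = rng.uniform(0.0, 2 * np.pi)
        s_global = rng.uniform(*scale_range) if scale is None else float(scale)
        tx_frac, ty_frac = rng.uniform(0.0, 1.0, size=2)
        elastic_field = elastic_displacement(rng, size) if elastic else None

        c = size / 2.0
        factor = downscale * s_global
        tform = (
            AffineTransform(translation=(-c, -c))
            + AffineTransform(scale=factor)
            + AffineTransform(rotation=angle)
            + AffineTransform(translation=(c, c))
        )
        moved = _warp_binary(src, tform)
        if elastic_field is not None:
            moved = _apply_elastic(moved, elastic_field)
        ys, xs = np.nonzero(moved)
        if len(ys) == 0:
            continue
        # translate so the lesion lands uniformly anywhere fully in frame
        y0, y1, x0, x1 = ys.min(), ys.max(), xs.min(), xs.max()
        margin = 2
        dy = int(round(-y0 + margin + ty_frac * max(size - (y1 - y0) - 2 * margin, 1)))
        dx = int(round(-x0 + margin + tx_frac * max(size - (x1 - x0) - 2 * margin, 1)))
        shifted = np.zeros_like(moved)
        ys2 = np.clip(ys + dy, 0, size - 1)
        xs2 = np.clip(xs + dx, 0, size - 1)
        shifted[ys2, xs2] = True
        out = _resample(shifted.astype(np.uint8), target_size)
        if out.sum() > 0:
            return PolypMask(
                grid=out,
                provenance={
                    **template.provenance,
                    "angle": float(angle),
                    "scale": s_global,
                },
            )
    raise PlacementError("transform produced an empty mask repeatedly")


def _resample(mask: np.ndarray, target: int) -> np.ndarray:
    if mask.shape[0] == target:
        return (mask > 0).astype(np.uint8)
    zoom = target / mask.shape[0]
    out = ndimage.zoom(mask.astype(np.float64), zoom, order=1)
    out = out[:target, :target]
    if out.shape[0] < target:  # pragma: no cover - zoom rounding guard
        out = np.pad(out, ((0, target - out.shape[0]), (0, target - out.shape[1])))
    return (out > 0.5).astype(np.uint8)


# ----------------------------------------------------------------- placement

def compute_valid_region(image: np.ndarray) -> np.ndarray:
    """Binary map of mucosal tissue: intensity thresholding that
    excludes near-black borders, overlays and corner thumbnails.

    The threshold is Otsu's, clamped into [20, 50] gray levels so that
    uniformly bright frames are fully valid while anything close to
    black is always excluded; a 3x3 opening drops speckle.
    """
    luma = (
        0.299 * image[..., 0] + 0.587 * image[..., 1] + 0.114 * image[..., 2]
    )
    try:
        otsu = float(threshold_otsu(luma))
    except ValueError:  # constant image
        otsu = 50.0
    thr = float(np.clip(otsu, 20.0, 50.0))
    valid = luma >= thr
    if valid.any() and not valid.all():
        valid = binary_opening(valid, footprint=np.ones((3, 3), dtype=bool))
    return valid.astype(np.uint8)


def place_mask(
    mt: PolypMask,
    mo: np.ndarray,
    rng: np.random.Generator | None = None,
    max_retries: int = 10,
    min_kept: float = 0.5,
    name: str = "<image>",
) -> PolypMask:
    """Final mask M = valid-region AND transformed mask; placement is
    re-drawn (random translation) when the intersection is empty or
    keeps less than half of the lesion area."""
    mo = (np.asarray(mo) > 0).astype(np.uint8)
    if mo.shape != mt.grid.shape:
        raise ValueError(f"shape mismatch {mo.shape} vs {mt.grid.shape}")
    rng = rng or np.random.default_rng(0)
    size = mo.shape[0]
    cur = mt.grid
    area = mt.area
    if area == 0:
        raise PlacementError(f"empty transformed mask for {name}")
    for _ in range(max_retries + 1):
        m = (mo & cur).astype(np.uint8)
        if m.sum() > 0 and m.sum() >= min_kept * area:
            return PolypMask(grid=m, provenance={**mt.provenance, "placed": True})
        ys, xs = np.nonzero(mt.grid)
        ty, tx = rng.uniform(0.0, 1.0, size=2)
        dy = int(-ys.min() + ty * max(size - (ys.max() - ys.min()) - 1, 1))
        dx = int(-xs.min() + tx * max(size - (xs.max() - xs.min()) - 1, 1))
        cur = np.zeros_like(mt.grid)
        cur[np.clip(ys + dy, 0, size - 1), np.clip(xs + dx, 0, size - 1)] = 1
    raise PlacementError(f"could not place lesion inside valid region of {name}")
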