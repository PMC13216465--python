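"""Inference and morphological post-processing.

The trained network produces an anomaly probability map at its working
resolution; it is resized back to the native frame size, thresholded,
and optionally refined: 5x5 morphological closing, hole filling, and
retention of the single largest connected component (the primary
lesion).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.morphology import closing as _closing
from skimage.transform import resize

from .memory_model import MapSegNet, MemoryBank

#: 8-connected foreground labelling (background holes are 4-connected)
_STRUCT8 = np.ones((3, 3), dtype=bool)


def predict(model: MapSegNet, bank: MemoryBank, image: np.ndarray,
            input_size: int | None = None) -> np.ndarray:
    """Probability raster at the image's native resolution."""
    if bank is None:
        raise ValueError("memory bank not built")
    model.eval()
    size = input_size or model.config.input_size
    h, w = image.shape[:2]
    if (h, w) != (size, size):
        resized = resize(image, (size, size), order=1, preserve_range=True,
                         anti_aliasing=True).astype(np.uint8)
    else:
        resized = image
    prob = model.forward(resized[None], bank)[0]
    if (h, w) != prob.shape:
        prob = resize(prob, (h, w), order=1, preserve_range=True)
    return np.clip(prob, 0.0, 1.0)


def binarize(prob: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    return (np.asarray(prob) >= threshold).astype(np.uint8)


def postprocess(mask: np.ndarray) -> np.ndarray:
    """Closing (5x5) -> fill enclosed holes -> keep largest component.

    Idempotent; an empty mask maps to an empty mask. Ties between
    equal-sized components keep the first in raster-scan label order.
    """
    m = np.asarray(mask) > 0
    if not m.any():
        return np.zeros_like(m, dtype=np.uint8)
    m = _closing(m, footprint=np.ones((5, 5), dtype=bool))
    m = ndimage.binary_fill_holes(m)
    labels, n = ndimage.label(m, structure=_STRUCT8)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        keep = 1 + int(np.argmax(sizes))  # argmax keeps the first on ties
        m = labels == keep
    return m.astype(np.uint8)


def segment(model: MapSegNet, bank: MemoryBank, image: np.ndarray,
            threshold: float = 0.5, refine: bool = True) -> dict:
    """Predict + binarize (+ refine); returns all three rasters."""
    prob = predict(model, bank, image)
    raw = binarize(prob, threshold)
    refined = postprocess(raw) if refine else raw
    return {"probability": prob, "raw": raw, "refined": refined}
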