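"""PNG image and binary-mask I/O (8-bit, via Pillow)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image


def imread(path) -> np.ndarray:
    """Read an image as uint8 RGB (H, W, 3)."""
    return np.asarray(Image.open(path).convert("RGB"))


def imwrite(path, image: np.ndarray) -> None:
    if image.dtype != np.uint8:
        raise ValueError("images are written as uint8")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(image).save(path)


def mask_read(path) -> np.ndarray:
    """Read a 0/255 PNG mask as a {0,1} uint8 array."""
    arr = np.asarray(Image.open(path).convert("L"))
    return (arr > 127).astype(np.uint8)


def mask_write(path, mask: np.ndarray) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray((np.asarray(mask) > 0).astype(np.uint8) * 255).save(path)
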