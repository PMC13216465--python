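"""Shared procedural fixtures (all generated at test time, seeded)."""

import numpy as np
import pytest

from mapseg.fixtures import MucosaSpec, TextureSpec, generate_mucosa, generate_texture
from mapseg.mask_gen import build_template_set


@pytest.fixture(scope="session")
def mucosa_images():
    """Six 128 px mucosa-like frames with varied appearance."""
    return [
        generate_mucosa(
            MucosaSpec(
                size=128,
                base_hue=float((340 + 5 * i) % 360),
                vignette_strength=0.2 + 0.1 * i,
                specular_count=i % 3,
                thumbnail="green" if i % 3 == 0 else "none",
                seed=100 + i,
            )
        )
        for i in range(6)
    ]


@pytest.fixture(scope="session")
def texture_images():
    return [
        generate_texture(TextureSpec(size=128, seed=200 + i, granularity=8.0 + 4 * i))
        for i in range(3)
    ]


@pytest.fixture(scope="session")
def templates_128():
    return build_template_set(count=6, seed=5, grid=128)


@pytest.fixture(scope="session")
def templates_64():
    return build_template_set(count=4, seed=7, grid=64)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
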