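import numpy as np
import pytest

from finstripe import ClassSpec, MaskedImage, generate_fish_image
from finstripe.preprocess import SENTINEL

BROWN = (140, 110, 60)
BLUE = (60, 80, 180)


def make_block_image(color_counts, width=40):
    """A masked image whose foreground is a pixel block with exact color
    counts, background sentinel elsewhere."""
    total = sum(c for _, c in color_counts)
    height = -(-total // width)
    pixels = np.empty((height + 2, width + 2, 3), dtype=np.uint8)
    pixels[:] = SENTINEL
    flat = []
    for rgb, count in color_counts:
        flat.extend([rgb] * count)
    flat = np.asarray(flat, dtype=np.uint8)
    body = np.empty((height * width, 3), dtype=np.uint8)
    body[:] = SENTINEL
    body[: len(flat)] = flat
    body = body.reshape(height, width, 3)
    pixels[1 : height + 1, 1 : width + 1] = body
    return MaskedImage.from_raster(pixels)


@pytest.fixture
def two_color_spec():
    return ClassSpec(label="two", palette=[(BROWN, 0.6), (BLUE, 0.4)],
                     stripe_count=0, body_width_px=200, body_height_px=60)


@pytest.fixture
def striped_spec():
    return ClassSpec(label="bars", palette=[(BROWN, 0.7), (BLUE, 0.3)],
                     stripe_count=3, stripe_orientation="vertical",
                     body_width_px=200, body_height_px=60)


@pytest.fixture
def two_color_image(two_color_spec):
    return generate_fish_image(two_color_spec, seed=1)


@pytest.fixture
def striped_image(striped_spec):
    return generate_fish_image(striped_spec, seed=2)
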