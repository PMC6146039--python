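import numpy as np
import pytest

from platephen.plate_io import PlateImage, PlateLayout


@pytest.fixture(scope="session")
def small_layout() -> PlateLayout:
    """A 2x3-well plate, large enough for a handful of seeds per well."""
    return PlateLayout(2, 3, (70.0, 70.0), 140.0, 66.0, "circle", "mini")


def make_image(layout: PlateLayout, color=(0.8, 0.8, 0.75), timestamp_h=0.0) -> PlateImage:
    shape = layout.image_shape()
    pix = np.empty(shape + (3,))
    for ch in range(3):
        pix[:, :, ch] = color[ch]
    return PlateImage(pix, timestamp_h, layout)


def paint_ellipse(image: PlateImage, center, axes, theta=0.0, color=(0.3, 0.2, 0.1)) -> None:
    cy, cx = center
    a, b = axes
    ext = int(np.ceil(max(a, b))) + 1
    rr, cc = np.mgrid[int(cy) - ext:int(cy) + ext + 1, int(cx) - ext:int(cx) + ext + 1]
    dy, dx = rr - cy, cc - cx
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    image.pixels[rr[inside], cc[inside]] = color


@pytest.fixture()
def blank_image(small_layout) -> PlateImage:
    return make_image(small_layout)
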