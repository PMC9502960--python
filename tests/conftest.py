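import numpy as np
import pytest

from chorioconcord import ImageFrame, RegionOfInterest


@pytest.fixture
def unit_frame() -> ImageFrame:
    """100x100 px frame over 1x1 mm (px area 1e-4 mm^2)."""
    return ImageFrame(100, 100, 1.0, 1.0)


@pytest.fixture
def frame_1024() -> ImageFrame:
    return ImageFrame(1024, 1024, 12.0, 12.0)


def square_roi(x0: float, y0: float, side: float, **kw) -> RegionOfInterest:
    return RegionOfInterest(
        [np.array([(x0, y0), (x0 + side, y0), (x0 + side, y0 + side), (x0, y0 + side)])],
        **kw,
    )


def random_simple_polygon(rng: np.random.Generator, n_min=5, n_max=16,
                          radius=(10.0, 40.0), center=(64.0, 64.0)) -> np.ndarray:
    """Star-shaped (hence simple) polygon with random vertex count/radii."""
    k = int(rng.integers(n_min, n_max + 1))
    th = np.sort(rng.uniform(0, 2 * np.pi, k))
    r = rng.uniform(*radius, size=k)
    c = np.asarray(center, float) + rng.uniform(-5, 5, 2)
    return np.column_stack([c[0] + r * np.cos(th), c[1] + r * np.sin(th)])
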