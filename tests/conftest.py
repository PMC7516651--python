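import numpy as np
import pytest

from enmiqa import GrayscaleImage, NeighborhoodSpec, default_spec


def random_image(rng, max_side=16, max_intensity=255):
    h = int(rng.integers(3, max_side + 1))
    w = int(rng.integers(3, max_side + 1))
    return GrayscaleImage(rng.integers(0, max_intensity + 1, size=(h, w)))


def brute_force_count(image: GrayscaleImage, t: int, nbhd: NeighborhoodSpec) -> int:
    """Literal double sum of the thresholded extremum test over interior pixels.

    Independent oracle: loops every pixel and every neighbor, applying the
    strict-inequality test exactly as written.
    """
    px = image.pixels
    total = 0
    for a in range(1, image.height - 1):
        for b in range(1, image.width - 1):
            center = px[a, b]
            if all(center > px[a + i, b + j] + t for i, j in nbhd.offsets):
                total += 1
            elif all(center < px[a + i, b + j] - t for i, j in nbhd.offsets):
                total += 1
    return total


@pytest.fixture
def rng():
    return np.random.default_rng(20220)


@pytest.fixture
def phantom_spec():
    return default_spec()


@pytest.fixture
def four():
    return NeighborhoodSpec.four()


@pytest.fixture
def eight():
    return NeighborhoodSpec.eight()
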