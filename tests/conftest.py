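import numpy as np
import pytest

from modmap import REDUCED_SCENE, PlanarImage, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_image(rng):
    """Small random image with an irregular mask, for brute-force oracles."""
    pixels = rng.uniform(0.5, 2.0, (32, 32))
    mask = np.ones((32, 32), dtype=bool)
    mask[:3, :] = False           # straight tissue edge
    mask[20:26, 4:9] = False      # interior hole
    return PlanarImage(pixels, pixel_size_um=5.0, mask=mask)


@pytest.fixture(scope="session")
def reduced_scene():
    """One default reduced-scale scene shared across read-only tests."""
    return generate_scene(42, REDUCED_SCENE)


def brute_force_disc_mean(pixels, mask, radius_px):
    """Explicit per-pixel disc enumeration (independent oracle)."""
    h, w = pixels.shape
    out = np.zeros((h, w))
    r = int(np.floor(radius_px))
    r2 = radius_px * radius_px * (1 + 1e-12)
    for i in range(h):
        for j in range(w):
            vals = []
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    if di * di + dj * dj <= r2:
                        ii, jj = i + di, j + dj
                        if 0 <= ii < h and 0 <= jj < w and mask[ii, jj]:
                            vals.append(pixels[ii, jj])
            out[i, j] = np.mean(vals) if vals else 0.0
    return out
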