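import numpy as np
import pytest

import sonartex as st
from sonartex.synth import default_scene
from sonartex.texture import GlcmParams, sliding_texture_grid


@pytest.fixture(scope="session")
def scene():
    """The package's reference synthetic scene (seeded)."""
    raster, polys = default_scene(seed=1)
    return raster, polys


@pytest.fixture(scope="session")
def scene_texture(scene):
    raster, polys = scene
    tex = sliding_texture_grid(raster, GlcmParams())
    return raster, polys, tex


@pytest.fixture(scope="session")
def calibration(scene_texture):
    _, polys, tex = scene_texture
    return st.build_calibration(tex, polys, B=1000, seed=0)


@pytest.fixture()
def worked_window():
    """The 4x4 two-by-two-block image whose d=1, theta=0 GLCM is known in
    closed form (12 pairs, six cells of probability 1/6)."""
    img = np.array(
        [[0, 0, 1, 1], [0, 0, 1, 1], [2, 2, 3, 3], [2, 2, 3, 3]]
    )
    return img, np.ones_like(img, dtype=bool)


def brute_force_glcm(window, mask, params):
    """Independent pair-enumeration oracle for the GLCM (pure python loops)."""
    N = params.N
    dr, dc = params.offset
    V = np.zeros((N, N), dtype=int)
    rows, cols = window.shape
    for r in range(rows):
        for c in range(cols):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < rows and 0 <= c2 < cols and mask[r, c] and mask[r2, c2]:
                V[window[r, c], window[r2, c2]] += 1
    if params.symmetric:
        V = V + V.T
    n = V.sum()
    P = V / n if n else V.astype(float)
    return P, int(n)
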