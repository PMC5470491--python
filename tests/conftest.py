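import numpy as np
import pytest

import sonosal as ss


@pytest.fixture(scope="session")
def easy_phantom() -> ss.Phantom:
    """Clean phantom: one dark elliptical lesion on a speckled background."""
    return ss.generate(ss.PhantomSpec(seed=0))


@pytest.fixture(scope="session")
def fat_band_phantom() -> ss.Phantom:
    """Phantom whose low-echo top band out-competes the lesion in saliency,
    so the first fixation must be rejected by the edge-junction check."""
    spec = ss.PhantomSpec(
        lesion_center=(89.0, 167.0), lesion_axes=(37.0, 35.0),
        lesion_gray=54.0, background_gray=152.0,
        fat_band=ss.FatBand(height=38, gray=21.0),
        speckle=0.2, seed=15,
    )
    return ss.generate(spec)


@pytest.fixture(scope="session")
def noisefree_lesion():
    """Noise-free 257x257 image: dark ellipse on a uniform bright field,
    with its exact mask.  Odd side keeps pyramid levels odd-sized."""
    h = w = 257
    img = np.full((h, w), 160.0)
    rr, cc = np.indices((h, w))
    mask = ((rr - 130) / 30.0) ** 2 + ((cc - 120) / 24.0) ** 2 <= 1.0
    img[mask] = 45.0
    return img, mask
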