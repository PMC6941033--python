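import numpy as np
import pytest
from skimage.draw import ellipse as draw_ellipse

from erymorph.synthetic import MixtureSpec, generate_feature_table


@pytest.fixture(scope="session")
def default_mixture() -> MixtureSpec:
    return MixtureSpec()


@pytest.fixture(scope="session")
def mixture_table(default_mixture):
    """One panel-sized draw from the default mixture (shared, read-only)."""
    return generate_feature_table(default_mixture, 4017, seed=11)


def make_ellipse_image(
    r_px: float,
    ratio: float = 1.0,
    theta: float = 0.0,
    pad: int = 30,
    cell_level: int = 100,
    background: int = 220,
) -> np.ndarray:
    """Noise-free image of a single digital ellipse (semi-minor r_px)."""
    a = r_px * ratio
    n = int(2 * (a + pad))
    img = np.full((n, n), float(background))
    rr, cc = draw_ellipse(n / 2, n / 2, r_px, a, shape=img.shape, rotation=theta)
    img[rr, cc] = cell_level
    return img.astype(np.uint8)
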