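import numpy as np
import pytest
from hypothesis import settings

from cryoclem.io import ChannelImage

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def sampled_gaussian_image(size, amp, x0, y0, sx, sy, background=(0.0, 0.0, 0.0),
                           channel="green", pixel_size_nm=103.0):
    """Noiseless image of the fit's own model class: a point-sampled Gaussian
    plus a linear background plane.  Used for in-model recovery tests."""
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    b0, b1, b2 = background
    img = (amp * np.exp(-((xx - x0) ** 2 / (2 * sx**2) + (yy - y0) ** 2 / (2 * sy**2)))
           + b0 + b1 * xx + b2 * yy)
    return ChannelImage(img, channel, pixel_size_nm)


def integrated_spot_image(size, photons, x0, y0, sigma_px, background=0.0,
                          channel="green", pixel_size_nm=103.0, rng=None):
    """Pixel-integrated Gaussian emitter (erf differences), optionally with
    Poisson noise — the physically faithful rendering used by the generator."""
    from scipy.special import erf

    xs = np.arange(size, dtype=float)
    fx = 0.5 * (erf((xs - x0 + 0.5) / (np.sqrt(2) * sigma_px))
                - erf((xs - x0 - 0.5) / (np.sqrt(2) * sigma_px)))
    fy = 0.5 * (erf((xs - y0 + 0.5) / (np.sqrt(2) * sigma_px))
                - erf((xs - y0 - 0.5) / (np.sqrt(2) * sigma_px)))
    expected = background + photons * np.outer(fy, fx)
    img = expected if rng is None else rng.poisson(expected).astype(float)
    return ChannelImage(img, channel, pixel_size_nm)


def similarity_matrix(scale, rotation_rad):
    c, s = np.cos(rotation_rad), np.sin(rotation_rad)
    return scale * np.array([[c, -s], [s, c]])


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
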