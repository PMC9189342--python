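import numpy as np
import pytest

from scomorph.io import ChannelStack
from scomorph.simulate import TissueSimParams, simulate_tissue_image


@pytest.fixture(scope="session")
def small_scene():
    """A modest noisy tissue field (1 glomerulus, 12 nuclei) with ground truth."""
    params = TissueSimParams(image_size_px=(512, 512), n_glomeruli=1,
                             glom_radius_um=18.0, n_nuclei=12, seed=11)
    return simulate_tissue_image(params)


@pytest.fixture(scope="session")
def noiseless_scene():
    """Same layout without shot/read noise, for exact-recovery checks."""
    params = TissueSimParams(image_size_px=(512, 512), n_glomeruli=1,
                             glom_radius_um=18.0, n_nuclei=12,
                             poisson_scale=0.0, read_noise_sd=0.0, seed=11)
    return simulate_tissue_image(params)


def make_stack(image: np.ndarray, pixel_size_um: float = 0.189,
               image_id: str = "fixture") -> ChannelStack:
    """Wrap a single 2D image as a 4-channel stack (same image everywhere)."""
    return ChannelStack(np.stack([image] * 4), pixel_size_um=pixel_size_um,
                        image_id=image_id)


def gaussian_spot_image(shape, x0, y0, sigma=1.5, amplitude=100.0, background=10.0):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
    return background + amplitude * np.exp(
        -((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * sigma**2))
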