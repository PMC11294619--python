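import numpy as np
import pytest
from hypothesis import settings

import histoquant as hq

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def noiseless_params():
    return hq.CellImageParams(gaussian_noise_sd=0.0, poisson_noise=False, seed=7)


@pytest.fixture(scope="session")
def noiseless_cell(noiseless_params):
    """One noiseless synthetic neuron image with its catalogue."""
    return hq.generate_cell_image(noiseless_params)


def make_rect_cell(ratio: float, cell_id: str = "cell") -> hq.AnnotatedImage:
    """A rectangular cell whose cytoplasm:nucleus pixel ratio is exact.

    Nucleus is a 10×10 block; the soma extends it by ``ratio``×100 cytoplasm
    pixels. A single bright 3×3 spot sits in the cytoplasm so detection with
    a fixed threshold finds exactly one punctum.
    """
    extra_cols = int(round(ratio * 10))
    h, w = 20, 20 + extra_cols + 10
    soma = np.zeros((h, w), dtype=bool)
    nucleus = np.zeros((h, w), dtype=bool)
    nucleus[5:15, 5:15] = True
    soma[5:15, 5:15 + extra_cols] = True
    channel = np.zeros((h, w))
    if extra_cols >= 6:
        channel[9:12, 15 + extra_cols - 5:15 + extra_cols - 2] = 10.0
    return hq.AnnotatedImage(channels={"puncta": channel}, pixel_size_um=1.0,
                             soma_mask=soma, nucleus_mask=nucleus,
                             z_plane_id=cell_id)


@pytest.fixture()
def rect_cell_set():
    """Cells with cytoplasm:nucleus ratios 1.0, 1.5, 2.0 and 3.0."""
    return {f"ratio_{r}": make_rect_cell(r) for r in (1.0, 1.5, 2.0, 3.0)}
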