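import numpy as np
import pytest

from morphoscreen import (
    AcquisitionParams,
    DoseResponseModel,
    PhenotypeParams,
    render_cell_image,
)


@pytest.fixture(scope="session")
def model():
    return DoseResponseModel()


@pytest.fixture(scope="session")
def acq():
    return AcquisitionParams()


@pytest.fixture(scope="session")
def clean_acq():
    """Noise-free acquisition for exact-value checks."""
    return AcquisitionParams(noise_sd=0.0)


def make_disk(radius=20, size=64, value=1.0):
    """Binary disk mask (and matching intensity image) for shape oracles."""
    yy, xx = np.mgrid[0:size, 0:size]
    c = (size - 1) / 2
    mask = (yy - c) ** 2 + (xx - c) ** 2 <= radius ** 2
    return mask, np.where(mask, value, 0.0)


@pytest.fixture(scope="session")
def rendered_cell(clean_acq):
    """A representative noiseless synthetic cell with texture."""
    phen = PhenotypeParams()
    return render_cell_image(phen, clean_acq, seed=42)
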