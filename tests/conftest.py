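import pytest

from sweeprestore.datasets import default_spec_for_size, generate_dataset
from sweeprestore.optics import Phantom, Spheroid


@pytest.fixture(scope="session")
def small_spec():
    """Desk-scale acquisition: 64x64 field at 4 um/px over a 750 um range."""
    return default_spec_for_size((64, 64))


@pytest.fixture(scope="session")
def single_phantom():
    """One bright spheroid centered in a 256x256x750 um volume."""
    return Phantom((256.0, 256.0, 750.0),
                   (Spheroid((128.0, 128.0, 375.0), 60.0, 5.0),),
                   background_rate=0.0, layout_kind="single")


@pytest.fixture(scope="session")
def multi_pairs(small_spec):
    """Six noisy single-plane-multi (S, P) pairs at 64x64."""
    pairs, phantoms = generate_dataset("single_plane_multi", 6, (64, 64), seed=7,
                                       spec=small_spec)
    return pairs, phantoms
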