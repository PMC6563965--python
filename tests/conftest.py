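import numpy as np
import pytest
from hypothesis import settings

from venoprf.hemodynamics import HRFModel, reference_waveform
from venoprf.stimulus import make_protocol, render_apertures
from venoprf.synthetic import PatchSpec, make_bundle

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def hrf():
    return HRFModel()


@pytest.fixture(scope="session")
def fullfield_protocol():
    return make_protocol("fullfield")


@pytest.fixture(scope="session")
def reference(fullfield_protocol, hrf):
    return reference_waveform(fullfield_protocol, hrf)


@pytest.fixture(scope="session")
def movies41():
    """Mapping + control apertures on a coarse 41-sample grid (fast)."""
    return {name: render_apertures(make_protocol(name), 41)
            for name in ("bowtie", "ring", "bar", "fullfield")}


@pytest.fixture(scope="session")
def bundle_small():
    """Default noisy scenario at test scale (20 x 20 lattice)."""
    return make_bundle(PatchSpec(rows=20, cols=20, seed=7), grid_samples=41)


@pytest.fixture(scope="session")
def bundle_noiseless():
    """Default scenario with the noise switched off (20 x 20 lattice)."""
    spec = PatchSpec(rows=20, cols=20, seed=11, noise_sd=0.0,
                     nbr_noise_sd=0.0)
    return make_bundle(spec, grid_samples=41)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
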