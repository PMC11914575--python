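import numpy as np
import pytest

from angiodl.synth import make_synthetic_slide, make_vessel_patch


@pytest.fixture(scope="session")
def vessel_patch():
    """A 64 px patch with ~10% planted vessel area."""
    return make_vessel_patch(seed=7, size_px=64, target_fraction=0.10)


@pytest.fixture(scope="session")
def slide_fixtures():
    """Ten small zero-noise slides spanning low to high vascularity."""
    fracs = np.linspace(0.01, 0.3, 10)
    return [make_synthetic_slide(seed=100 + i, n_patches=2, slide_fraction=float(f),
                                 noise_sd=0.0, size_px=64)
            for i, f in enumerate(fracs)]


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
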