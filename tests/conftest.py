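import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracle_utils importable

from fetquant import PhantomSpec, generate_phantom
from fetquant.phantom import TumorFocus


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """A 48^3, 3 mm phantom: one 12 mm focus at contrast 3, noiseless."""
    return PhantomSpec(
        grid_shape=(48, 48, 48),
        spacing=(3.0, 3.0, 3.0),
        tumor_foci=(TumorFocus(center_vox=(31, 27, 25), radius_mm=12.0, contrast=3.0),),
        noise_sd=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_scene(small_spec):
    return generate_phantom(small_spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
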