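import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from smearkit.classifier import CLASS_NAMES
from smearkit.synthetic import SmearSpec, generate_smear


@pytest.fixture(scope="session")
def small_smear():
    """One 128x128 smear with one cell per class and moderate overlap."""
    spec = SmearSpec(height=128, width=128,
                     cells_per_class={n: 1 for n in CLASS_NAMES},
                     overlap_fraction=0.2, seed=42)
    return generate_smear(spec)


@pytest.fixture(scope="session")
def clean_smear():
    """Noise- and gradient-free smear: pixel provenance is exact."""
    spec = SmearSpec(height=128, width=128,
                     cells_per_class={n: 1 for n in CLASS_NAMES},
                     overlap_fraction=0.2, noise_sigma=0.0,
                     illumination_gradient=0.0, seed=42)
    return generate_smear(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
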