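import numpy as np
import pytest

from xvlung import LungMask, VentilationVolume
from xvlung.synth import TumorFociSpec, VirtualLung, generate_phase_series


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_volume_and_mask(rng):
    """Random 5x5x5 SV field with a random ~half mask (unit spacing)."""
    values = rng.uniform(0.01, 0.5, size=(5, 5, 5))
    mask = rng.random((5, 5, 5)) < 0.5
    mask.flat[0] = True  # never empty
    return VentilationVolume(values, spacing=(1.0, 1.0, 1.0)), LungMask(mask)


@pytest.fixture(scope="session")
def tumor_phantom():
    """One simulated animal with planted slow-filling foci."""
    lung = VirtualLung()
    foci = TumorFociSpec(n_foci=4, severity=0.6, fill_delay=1.0, seed=7)
    return generate_phase_series(lung, foci)


@pytest.fixture(scope="session")
def null_phantom():
    lung = VirtualLung()
    foci = TumorFociSpec(n_foci=0, severity=0.0, seed=7)
    return generate_phase_series(lung, foci)
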