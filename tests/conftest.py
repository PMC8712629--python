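import numpy as np
import pytest

from nglyco.process import default_calibrants, preprocess, recalibrate
from nglyco.registry import CompositionRegistry
from nglyco.sim import InstrumentModel, default_baseline


@pytest.fixture(scope="session")
def registry():
    return CompositionRegistry.default()


@pytest.fixture(scope="session")
def baseline(registry):
    return default_baseline(registry)


@pytest.fixture(scope="session")
def calibrants(registry, baseline):
    return default_calibrants(registry, baseline.to_dict())


@pytest.fixture(scope="session")
def clean_instrument():
    """Noise-free, baseline-free, drift-free instrument for exactness checks."""
    return InstrumentModel(noise_sd=0.0, baseline_amplitude=0.0,
                           drift_ppm=(0.0, 0.0, 0.0),
                           drift_jitter_ppm=(0.0, 0.0, 0.0), scale_cv=0.0)


@pytest.fixture(scope="session")
def realistic_instrument():
    """Default noisy instrument but with a fixed (jitter-free) drift."""
    return InstrumentModel(drift_ppm=(25.0, 5.0, 0.0),
                           drift_jitter_ppm=(0.0, 0.0, 0.0), scale_cv=0.0)


def process_spectrum(spec, calibrants):
    return recalibrate(preprocess(spec), calibrants)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
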