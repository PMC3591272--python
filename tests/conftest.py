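import numpy as np
import pytest
from hypothesis import settings

from utr3end import simulate

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_library():
    """A 20-construct synthetic library with planted truth (session-cached)."""
    return simulate.generate_construct_library(20, seed=101)


@pytest.fixture(scope="session")
def small_plate():
    """A 5-strain simulated plate with mild noise (session-cached)."""
    production = {f"s{i}": p for i, p in enumerate(np.linspace(0.5, 3.0, 5))}
    samples, backgrounds, truth = simulate.simulate_plate_timecourses(
        production, noise_frac=0.01, spike_rate=0.0, seed=202
    )
    return production, samples, backgrounds, truth
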