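import numpy as np
import pytest

from cochstream import (
    CochlearGeometry,
    FlowNumerics,
    Stimulus,
    compute_drift,
    solve_oscillatory_flow,
    synthesize_wave,
)


@pytest.fixture(scope="session")
def geom():
    return CochlearGeometry()


@pytest.fixture(scope="session")
def small_geom():
    """Reduced-resolution domain for fast flow unit tests."""
    return CochlearGeometry(
        length_m=12e-3, h_corti_m=80e-6, h_scala_m=200e-6,
        nx=120, ny_corti=8, ny_scala=20,
    )


@pytest.fixture(scope="session")
def small_active_solution(small_geom):
    stim = Stimulus(kind="tone", frequency_hz=1000.0, level_db_spl=80.0)
    wave = synthesize_wave(small_geom, stim, ohc_active=True)
    return solve_oscillatory_flow(
        small_geom, wave, numerics=FlowNumerics(max_periods=15)
    )


@pytest.fixture(scope="session")
def small_active_drift(small_active_solution):
    return compute_drift(small_active_solution)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
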