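import numpy as np
import pytest

from eegfmri.simulate import (
    add_mr_artifacts,
    make_head_model,
    project_to_sensors,
    simulate_sources,
)


@pytest.fixture(scope="session")
def small_head():
    """16-sensor head over a 4×4×3 grid — enough geometry for unit tests."""
    return make_head_model(n_sensors=16, grid_shape=(4, 4, 3), spacing_mm=6.0,
                           seed=11)


@pytest.fixture(scope="session")
def standard_head():
    """32-sensor head over a 6×6×5 grid, the standard cleaning fixture size."""
    return make_head_model(n_sensors=32, grid_shape=(6, 6, 5), spacing_mm=6.0,
                           seed=5)


@pytest.fixture(scope="session")
def clean_subject(standard_head):
    """Noise-free alpha-network subject projected to sensors (160 s @ 200 Hz)."""
    grid, leadfield = standard_head
    sources, truth = simulate_sources(
        grid, K=1, band_assignment=("alpha",), duration_s=160.0, fs=200.0,
        seed=6)
    rec = project_to_sensors(leadfield, sources)
    return {"grid": grid, "leadfield": leadfield, "sources": sources,
            "truth": truth, "rec": rec}


@pytest.fixture(scope="session")
def contaminated_subject(clean_subject):
    """The clean subject plus the full MR artifact load (default amplitudes)."""
    rec = add_mr_artifacts(clean_subject["rec"], tr_s=2.0, seed=10)
    return {**clean_subject, "dirty": rec}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
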