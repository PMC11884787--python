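import numpy as np
import pytest

from moviemap.sheet import build_cortical_sheet, generate_ground_truth_maps, trace_gradient_lines
from moviemap.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def sheet():
    return build_cortical_sheet(24, 32)


@pytest.fixture(scope="session")
def maps(sheet):
    return generate_ground_truth_maps(sheet)


@pytest.fixture(scope="session")
def lines_parallel(sheet):
    return trace_gradient_lines(sheet, "parallel")


@pytest.fixture(scope="session")
def lines_perpendicular(sheet):
    return trace_gradient_lines(sheet, "perpendicular")


@pytest.fixture(scope="session")
def small_bundle():
    """A small but fully structured cohort for fast end-to-end tests."""
    return simulate_cohort(
        SimulationConfig(n_participants=4, n_timepoints=60, n_movies=1, seed=11)
    )


@pytest.fixture(scope="session")
def default_bundle():
    """The package's standard cohort (study conditions)."""
    return simulate_cohort(SimulationConfig())


def make_recording(data, tr=2.0, maps=None, loadings=None):
    """Wrap a plain array as a single-movie ParticipantRecording."""
    from moviemap.simulate import ParticipantRecording
    from moviemap.sheet import GroundTruthMaps

    data = np.asarray(data, dtype=float)
    n_units, t = data.shape
    if maps is None:
        maps = GroundTruthMaps(
            spatial_frequency=np.zeros(n_units), meridian=np.zeros(n_units)
        )
    if loadings is None:
        loadings = np.zeros((n_units, 1))
    return ParticipantRecording(
        data=data,
        tr=tr,
        movie_intervals=((0, t),),
        motion=np.zeros(t),
        seed=0,
        participant=0,
        loadings=loadings,
        maps=maps,
    )
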