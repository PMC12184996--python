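import numpy as np
import pytest

from stressface import AppConfig, CleaningConfig, WindowConfig, clean_trajectories
from stressface.keypoint_io import TrajectoryTable
from stressface.landmarks import LANDMARKS, N_LANDMARKS
from stressface.session_simulator import SimulationConfig, simulate_session


@pytest.fixture(scope="session")
def config():
    return AppConfig()


@pytest.fixture(scope="session")
def wconfig():
    return WindowConfig()


def _clean_session(seed, schedule=None, duration_s=30.0):
    sim = simulate_session(
        SimulationConfig(seed=seed, duration_s=duration_s, state_schedule=schedule)
    )
    return sim, clean_trajectories(sim.table, CleaningConfig())


@pytest.fixture(scope="session")
def relaxed_session():
    """(SimulatedSession, cleaned table) for a fully relaxed 30 s session."""
    return _clean_session(seed=11)


@pytest.fixture(scope="session")
def stressed_session():
    """(SimulatedSession, cleaned table): squint + freeze + ear fold."""
    return _clean_session(seed=12, schedule=[("stressed_combined", 30.0)])


@pytest.fixture(scope="session")
def squint_session():
    return _clean_session(seed=13, schedule=[("stressed_squint", 30.0)])


@pytest.fixture(scope="session")
def freeze_session():
    return _clean_session(seed=14, schedule=[("stressed_freeze", 30.0)])


@pytest.fixture(scope="session")
def fold_session():
    """Relaxed lead-in so the session-median ear position is unpinned."""
    return _clean_session(
        seed=15, schedule=[("relaxed", 20.0), ("stressed_ear_fold", 10.0)]
    )


def still_table(n_frames=60, fps=30.0, likelihood=1.0):
    """A motionless, fully-confident table with plausible geometry."""
    base = {
        "ear_left": (860.0, 420.0),
        "ear_right": (1060.0, 420.0),
        "eyelid_upper_left": (910.0, 530.0),
        "eyelid_lower_left": (910.0, 550.0),
        "eyelid_upper_right": (1010.0, 530.0),
        "eyelid_lower_right": (1010.0, 550.0),
        "nose": (960.0, 700.0),
    }
    xy = np.empty((n_frames, N_LANDMARKS, 2))
    for j, lm in enumerate(LANDMARKS):
        xy[:, j] = base[lm.value]
    lik = np.full((n_frames, N_LANDMARKS), likelihood)
    return TrajectoryTable(xy, lik, fps=fps)
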