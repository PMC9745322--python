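import numpy as np
import pytest

from autcage import agents, identification, io, schedule, staircase


@pytest.fixture(scope="session")
def default_schedule():
    return schedule.build_schedule()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def group_logs(tmp_path_factory):
    """Three simulated sessions of a 3-subject group with a noisy identifier.

    Shared by analysis and IO tests; regenerated deterministically from a
    fixed seed at collection time.
    """
    sch = schedule.build_schedule()
    subjects = ["B", "K", "L"]
    conf = np.array([
        [0.92, 0.02, 0.02, 0.04],
        [0.02, 0.92, 0.02, 0.04],
        [0.02, 0.02, 0.92, 0.04],
    ])
    ident = identification.IdentityModel(subjects, conf)
    group = agents.GroupSchedule(subjects=tuple(subjects), session_duration=3600.0)
    agent_map = {s: agents.AgentParams(s) for s in subjects}
    store = staircase.ProgressStore(tmp_path_factory.mktemp("store") / "progress.json")
    rng = np.random.default_rng(20220)
    logs = []
    for i in range(3):
        logs.append(agents.simulate_session(
            group, agent_map, sch, store, ident, rng,
            session_id=f"S{i + 1:03d}", start_time=i * 3600.0))
    return logs


@pytest.fixture(scope="session")
def group_frame(group_logs):
    return io.logs_to_frame(group_logs)
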