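from datetime import datetime

import pytest

from pcmckit import synthetic_data as sd
from pcmckit.behavior_io import EventRecord, PCMCPair, Session


def make_session(
    session_id="s1",
    kind="PC",
    focal="A",
    opponent="B",
    focal_role="victim",
    date_time=datetime(2013, 6, 1, 10, 0),
    conflict_physical=False,
    conflict_counter=False,
    events=(),
):
    return Session(
        session_id=session_id,
        kind=kind,
        focal=focal,
        opponent=opponent,
        focal_role=focal_role,
        date_time=date_time,
        conflict_physical=conflict_physical,
        conflict_counter=conflict_counter,
        events=sorted(events, key=lambda e: e.t),
    )


def make_event(session_id="s1", t=10.0, actor="A", recipient="B", behavior="contact",
               oriented=None, distance=None):
    return EventRecord(
        session_id=session_id, t=t, actor=actor, recipient=recipient,
        behavior=behavior, oriented_at_recipient=oriented, distance_m=distance,
    )


def make_pair(pair_id="p1", pc=None, mc=None, **kwargs):
    pc = pc or make_session(session_id=f"{pair_id}_pc", kind="PC", **kwargs)
    mc = mc or make_session(
        session_id=f"{pair_id}_mc",
        kind="MC",
        date_time=pc.date_time.replace(day=pc.date_time.day + 2),
        **kwargs,
    )
    return PCMCPair(pair_id=pair_id, pc=pc, mc=mc)


@pytest.fixture(scope="session")
def small_dataset():
    """A small but non-trivial simulated dataset shared across tests."""
    config = sd.SimulationConfig(n_females=12, n_conflicts=80, census_sessions=60)
    return sd.simulate_dataset(config, seed=20130301)
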