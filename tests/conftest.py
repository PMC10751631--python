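from datetime import date, datetime

import pytest

from peernet.io_model import (
    CommunicationEvent,
    CommunityLog,
    EventKind,
    Member,
    Role,
    RoleInterval,
)
from peernet.synthetic import (
    EXAMPLE_CODE_MARGINS,
    EXAMPLE_EVENT_MARGINS,
    SimulationConfig,
    code_assignments_from_margins,
    fixture_from_margins,
    simulate_community,
)


def make_member(mid, join="2020-01-01", role=Role.REGULAR, exit_date=None, **kw):
    jd = date.fromisoformat(join)
    ed = date.fromisoformat(exit_date) if exit_date else None
    return Member(
        member_id=mid,
        join_date=jd,
        role_history=(RoleInterval(role, jd, ed),),
        exit_date=ed,
        **kw,
    )


def make_log(members, events, start="2020-01-01", end="2020-12-31"):
    return CommunityLog(
        members=members,
        events=events,
        observation_start=date.fromisoformat(start),
        observation_end=date.fromisoformat(end),
    ).validate()


@pytest.fixture
def tiny_log():
    """A posts; B comments on it; C views it."""
    members = [make_member(m) for m in ("A", "B", "C")]
    t = datetime(2020, 2, 1, 12, 0)
    events = [
        CommunicationEvent("p1", "A", EventKind.POST, t),
        CommunicationEvent("c1", "B", EventKind.COMMENT, t.replace(hour=13), "p1"),
        CommunicationEvent("v1", "C", EventKind.VIEW, t.replace(hour=14), "p1"),
    ]
    return make_log(members, events)


@pytest.fixture(scope="session")
def sim_default():
    """One default-configuration simulated community plus its ground truth."""
    return simulate_community(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def sim_batch():
    """Twenty default-configuration communities (seeds 0..19), shared by the
    calibration and recovery tests."""
    return [simulate_community(SimulationConfig(seed=s)) for s in range(20)]


@pytest.fixture(scope="session")
def analysis_batch(sim_batch):
    """Full-pipeline results for each community in sim_batch."""
    from peernet.pipeline import analyze

    return [(analyze(log), truth) for log, truth in sim_batch]


@pytest.fixture(scope="session")
def margins_log():
    """Log whose margins equal the printed community totals."""
    return fixture_from_margins(
        EXAMPLE_EVENT_MARGINS, n_members=222, n_connected=203, n_exited=26, n_leaders=10
    )


@pytest.fixture(scope="session")
def margins_codes():
    return code_assignments_from_margins(EXAMPLE_CODE_MARGINS)
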