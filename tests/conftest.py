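import numpy as np
import pytest

from leverseq import (
    AgentParams,
    BehaviorLog,
    CellSpec,
    ScheduleSpec,
    simulate_behavior,
    simulate_calcium,
)


@pytest.fixture
def fr1_schedule():
    return ScheduleSpec("FR1")


@pytest.fixture
def tc4_schedule():
    return ScheduleSpec("TC-FR4", ratio=4, time_limit_s=1.0)


@pytest.fixture
def simple_log():
    """Hand-built log: two multi-press runs and a single press."""
    return BehaviorLog(
        session_id="hand",
        presses=np.array([10.0, 10.3, 10.6, 10.9, 20.0, 20.5, 30.0]),
        head_entries=np.array([11.5]),
        rewards=np.array([]),
        schedule=ScheduleSpec("unknown"),
        duration_s=60.0,
    )


@pytest.fixture
def small_session(tc4_schedule):
    """Small seeded synthetic session with behavior and traces."""
    agent = AgentParams(n_seqs=40)
    log, gt = simulate_behavior(tc4_schedule, agent, seed=11)
    cells = [
        CellSpec("instant", latency_base_s=0.1, reliability=0.95),
        CellSpec("delayed", latency_base_s=0.8, duration_coupling=0.5, reliability=0.95),
    ]
    tm, gt = simulate_calcium(log, gt, cells, seed=12)
    return log, gt, tm
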