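import numpy as np
import pandas as pd
import pytest

from mhengage import SimConfig, generate_cohort


def make_events(minutes, pid="p1", origin="2024-10-01T00:00:00Z"):
    """Events at the given minute offsets from an origin instant."""
    base = pd.Timestamp(origin)
    return pd.DataFrame(
        {
            "participant_id": pid,
            "timestamp": [base + pd.Timedelta(minutes=m) for m in minutes],
        }
    )


def brute_force_sessions(minutes, tau):
    """Independent segmenter: scan adjacent gaps, split where gap >= tau."""
    if not len(minutes):
        return []
    sessions = [[minutes[0]]]
    for prev, cur in zip(minutes[:-1], minutes[1:]):
        if cur - prev >= tau:
            sessions.append([cur])
        else:
            sessions[-1].append(cur)
    return sessions


@pytest.fixture(scope="session")
def small_cohort():
    cfg = SimConfig(n_participants=8, seed=11, dropout_hazard_per_day=0.0,
                    events_per_session_mean=6.0)
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20240)
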