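import numpy as np
import pandas as pd
import pytest

from pupstate import synth, vocab
from pupstate.datatypes import EventLog


def make_log(bouts, duration=900.0, session="s1", subject="m1"):
    """EventLog from a list of (behaviour, onset, offset) tuples."""
    return EventLog(
        session, subject,
        pd.DataFrame(bouts, columns=["behaviour", "onset_s", "offset_s"]),
        assay_duration=duration,
    )


@pytest.fixture(scope="session")
def aggressive_log():
    prof = synth.default_profile("aggressive")
    return synth.gen_behavior_session(prof, 600.0, seed=11)


@pytest.fixture(scope="session")
def parental_log():
    prof = synth.default_profile("parental")
    return synth.gen_behavior_session(prof, 600.0, seed=12)


@pytest.fixture(scope="session")
def planted_shift_session(aggressive_log):
    """Traces with a persistent −5 population shift from the first attack."""
    spec = synth.TuningSpec(effects={}, state_shift=-5.0, noise_sd=1.0)
    tm, gt = synth.gen_trace_dataset(aggressive_log, 30, spec, 20.0, seed=13)
    return aggressive_log, tm, gt


@pytest.fixture
def rng():
    return np.random.default_rng(42)
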