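from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from mouseprl.task import BACK, FRONT, OMIT, SubjectDataset, TrialRecord

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_session(choices, high_lever=FRONT, subject_id="s1", phase="p", session=0,
                 rewarded=None):
    """Build a session's TrialRecords from a choice token list."""
    if rewarded is None:
        rewarded = [False] * len(choices)
    return [
        TrialRecord(
            subject_id=subject_id, phase_label=phase, session_index=session,
            trial_index=i, choice=c, high_lever=high_lever,
            rewarded=bool(r) and c != OMIT,
        )
        for i, (c, r) in enumerate(zip(choices, rewarded))
    ]


def make_dataset(sessions_choices, high_lever=FRONT, phase="p", subject_id="s1"):
    trials = []
    for s, choices in enumerate(sessions_choices):
        trials.extend(make_session(choices, high_lever, subject_id, phase, s))
    return SubjectDataset(subject_id=subject_id, trials=trials)


def oracle_reversals(choices, high_initial, run_length=8):
    """Window-scan reversal counter: an independent formulation.

    Finds the earliest contiguous window of ``run_length`` choices all equal
    to the current high lever, counts a reversal, flips the role, and resumes
    scanning after the window.  Omissions and low-lever choices both break a
    window.
    """
    high = high_initial
    n = 0
    i = 0
    while True:
        j = None
        for start in range(i, len(choices) - run_length + 1):
            if all(c == high for c in choices[start:start + run_length]):
                j = start
                break
        if j is None:
            return n
        n += 1
        high = BACK if high == FRONT else FRONT
        i = j + run_length


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
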