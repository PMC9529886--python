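import numpy as np
import pandas as pd
import pytest

from cognophen.syndata import SimConfig, case_control_fixture

CASES = ["M593", "M639", "M344"]
CONTROLS = ["M1486", "M1488", "M1140", "M1969"]


@pytest.fixture(scope="session")
def case_fixture():
    """The deterministic case/control screening fixture."""
    return case_control_fixture()


@pytest.fixture()
def toy_social_trials() -> pd.DataFrame:
    """Handcrafted social reversal table around one block transition.

    Block 2 (correct T2, previous T1) contains exactly one qualifying
    switch-error trial (index 2) and one qualifying choice-error trial
    (index 4).
    """
    cols = ["session_day", "block_id", "trial_in_block", "actor",
            "chosen_target", "correct_target_current",
            "correct_target_previous", "rewarded"]
    rows = [
        # block 1: no previous contingency
        (1, 1, 1, "self", "T1", "T1", None, True),
        (1, 1, 2, "partner", "T1", "T1", None, True),
        # block 2: correct T2, previous T1
        (1, 2, 1, "partner", "T1", "T2", "T1", False),  # switch error (chose prev correct)
        (1, 2, 2, "self", "T2", "T2", "T1", True),      # <- switch-error selection
        (1, 2, 3, "partner", "T3", "T2", "T1", False),  # choice error; T2 seen at t2
        (1, 2, 4, "self", "T2", "T2", "T1", True),      # <- choice-error selection
        (1, 2, 5, "partner", "T2", "T2", "T1", True),
        (1, 2, 6, "self", "T2", "T2", "T1", True),      # preceded by rewarded partner
        # block 3: correct T3, previous T2; partner errs before T3 ever chosen
        (1, 3, 1, "partner", "T1", "T3", "T2", False),  # switch trial but chose T1 != prev
        (1, 3, 2, "partner", "T2", "T3", "T2", False),  # choice error, correct never seen
        (1, 3, 3, "self", "T3", "T3", "T2", True),      # excluded by condition (2)
    ]
    return pd.DataFrame(rows, columns=cols)


def make_cfg(**kw) -> SimConfig:
    return SimConfig(**kw)
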