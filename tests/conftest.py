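import numpy as np
import pandas as pd
import pytest

from aacmodel import AgentParams, build_task_design, simulate_subject
from aacmodel.cohort import RTModel


@pytest.fixture(scope="session")
def design60():
    return build_task_design(seed=123)


@pytest.fixture(scope="session")
def subject_2_3(design60):
    """One simulated subject with du=2, ec=3 on the 60-trial design."""
    return simulate_subject(
        AgentParams(du=2.0, ec=3.0), design60, RTModel(), seed=42
    )


@pytest.fixture()
def hand_trials():
    """A tiny hand-constructed trials frame (3 trials)."""
    return pd.DataFrame(
        {
            "trial_index": [0, 1, 2],
            "trial_type": ["APP", "CONF4", "AV"],
            "high_cue_side": ["left", "right", "left"],
            "start_position": ["center", "left_end", "right_end"],
            "chosen_position": [9, 5, 1],
            "outcome_valence": ["positive", "positive", "positive"],
            "outcome_points": [2, 0, 0],
            "rt": [1.2, 2.0, 0.9],
        }
    )
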