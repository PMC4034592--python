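import numpy as np
import pytest

from dtlest import Scenario, TrialDesign
from dtlest.trial import TrialData, rank_and_select


@pytest.fixture(scope="session")
def design321():
    """3:2:1 design with 50 patients/arm/stage and v2=50 (all stage sds 1)."""
    return TrialDesign((3, 2, 1), (50, 50, 50), 50.0)


@pytest.fixture(scope="session")
def design_unequal():
    """3:2:1 design with per-stage sample sizes 100/50/25 and v2=50."""
    return TrialDesign((3, 2, 1), (100, 50, 25), 50.0)


@pytest.fixture(scope="session")
def null_scenario(design321):
    """All-zero means on the equal-allocation 3:2:1 design."""
    return Scenario(design=design321, means=(0.0, 0.0, 0.0), seed=1234, reps=1000)


def make_outcome(stage_means, design, mu_selected=None):
    """Build a SelectionOutcome from explicit stage means (NaN = inactive)."""
    trial = TrialData(stage_means=np.asarray(stage_means, dtype=float))
    outcome = rank_and_select(trial, design)
    if mu_selected is not None:
        outcome.mu_selected = float(mu_selected)
    return trial, outcome


@pytest.fixture(scope="session")
def outcome_321(design321):
    """A hand-fixed consistent 3:2:1 trial: arm 1 selected, arm 3 dropped."""
    stage_means = [
        [0.7, 0.5, 0.5],  # selected: z = 50*(0.7+0.5+0.5) = 85
        [0.4, 0.1, np.nan],  # runner-up: cumulative (20+5)/100 = 0.25
        [0.3, np.nan, np.nan],  # dropped at stage 1
    ]
    _, outcome = make_outcome(stage_means, design321, mu_selected=0.0)
    return outcome
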