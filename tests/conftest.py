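import sys
from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))  # tests.reference oracle

settings.register_profile(
    "ci", max_examples=50, deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from scfield import FieldParams, TrialSettings, TrialTimeline
from scfield.protocol import VARIED_ATTRIBUTES


@pytest.fixture(scope="session")
def params():
    return FieldParams()


@pytest.fixture(scope="session")
def timeline():
    return TrialTimeline()


def make_settings(task="pro", side="right", default="medium", **levels):
    """TrialSettings with every attribute at ``default`` unless overridden."""
    return TrialSettings(
        task=task, stimulus_side=side,
        levels=tuple(levels.get(a, default) for a in VARIED_ATTRIBUTES))


#: the worked correct-anti-saccade example trial (all eight inputs active)
FIG_TRIAL_LEVELS = dict(
    shared_onset_delay="large", automated_motor_ror="medium",
    automated_motor_max="medium", voluntary_motor_ror="large",
    voluntary_fixation_max="medium", voluntary_preparation_max="small",
    inhibitory_gate_ror="medium", inhibitory_gate_max="large",
    peripheral_inhibition_ror="medium", peripheral_inhibition_max="large")


@pytest.fixture(scope="session")
def worked_anti_settings():
    return make_settings(task="anti", **FIG_TRIAL_LEVELS)
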