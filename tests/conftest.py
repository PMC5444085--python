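import hypothesis
import numpy as np
import pandas as pd
import pytest

from vectorcycle import BehaviourProfile, Intervention
from vectorcycle.indicators import SurveyData

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=60, deadline=None
)
hypothesis.settings.load_profile("ci")


@pytest.fixture
def arabiensis_profile() -> BehaviourProfile:
    """A zoophilic, partly endophagic population: half of meals on humans,
    most human exposure indoors."""
    return BehaviourProfile(
        q_human=0.5,
        pi_indoor=0.9,
        pi_in_bed=0.8,
        f_livestock=0.9,
        r_indoor_rest=0.4,
        sugar_rate=0.3,
    )


@pytest.fixture
def llin() -> Intervention:
    return Intervention(kind="LLIN", coverage=0.8, pre_kill=0.2, block=0.5)


@pytest.fixture
def uniform_survey() -> SurveyData:
    """Equal biting rates everywhere, humans indoors exactly half of all
    person-time: indoor and outdoor exposure are symmetric."""
    return SurveyData(
        pd.DataFrame(
            {
                "hour": np.arange(24),
                "bite_rate_indoor": 1.0,
                "bite_rate_outdoor": 1.0,
                "frac_humans_indoor": 0.5,
                "frac_humans_in_bed": 0.25,
            }
        )
    )
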