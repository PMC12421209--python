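import hypothesis
import pytest

import jitaisim as js

hypothesis.settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("suite")


@pytest.fixture(scope="session")
def study_result():
    """One full pipeline run at the study's own scale (25 persons, 21 days)."""
    return js.run_pipeline(js.RunConfig(), seed=1)


@pytest.fixture()
def default_trigger():
    return js.TriggerConfig()
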