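import numpy as np
import pytest

from cvdcoi.synthetic import SurveyGeneratorConfig, gen_survey, load_fixtures


@pytest.fixture(scope="session")
def fixtures():
    """The packaged cost tables, margins and constants."""
    return load_fixtures()


@pytest.fixture(scope="session")
def survey_default():
    """One default-config survey draw plus its analytic truth."""
    return gen_survey(SurveyGeneratorConfig(n=20_000, seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
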