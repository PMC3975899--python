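import numpy as np
import pandas as pd
import pytest

from exitcost import default_spec, generate_donors, generate_survey, scaled_spec


@pytest.fixture(scope="session")
def spec_small():
    """Default study conditions scaled to a small sample."""
    return scaled_spec(1_200, seed=7)


@pytest.fixture(scope="session")
def survey_small(spec_small):
    return generate_survey(spec_small, seed=7)


@pytest.fixture(scope="session")
def donors_small(spec_small):
    return generate_donors(spec_small, 8_000, seed=11)


@pytest.fixture(scope="session")
def matched_small(spec_small, survey_small, donors_small):
    """Survey with calibrated weights and imputed economics."""
    from exitcost import calibrate_weights, generate_benchmarks, impute_economics

    benchmarks = generate_benchmarks(spec_small, ["age_group", "sex"])
    cal = calibrate_weights(survey_small, benchmarks)
    survey = survey_small.assign(weight=cal.weights)
    matched, _ = impute_economics(survey, donors_small, seed=13)
    return matched
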