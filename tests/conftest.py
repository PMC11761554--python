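import pytest

from relaxfit.models import TSLSchedule
from relaxfit.synthetic import ParamPrior, sample_parameters


@pytest.fixture(scope="session")
def schedule():
    return TSLSchedule()


@pytest.fixture(scope="session")
def random_params():
    """50 valid parameter draws per model from the default priors."""
    return {
        model: sample_parameters(ParamPrior(model), 50, seed=1234)
        for model in ("me", "be", "se")
    }
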