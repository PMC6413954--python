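import pytest
from hypothesis import settings

from gonogo import LearningParams

settings.register_profile("ci", derandomize=True, max_examples=200)
settings.load_profile("ci")


@pytest.fixture
def alternating_params() -> LearningParams:
    """Learning parameters tuned for the alternating +/-20 schedule
    (inverting the equilibrium coefficients at alpha=0.3, c_Q=0.7, c_S=0.9)."""
    return LearningParams(alpha=0.3, epsilon=0.443, lam=0.093)


@pytest.fixture
def two_action_params() -> LearningParams:
    """Learning parameters for the two-action softmax task
    (inverting the coefficients at alpha=0.4, c_Q=0.75, c_S=0.95)."""
    return LearningParams(alpha=0.4, epsilon=0.519, lam=0.1013)
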