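import pytest

from pursuitcircuit import MONKEY_RE, ModelParams


@pytest.fixture
def re_params() -> ModelParams:
    """Monkey-RE fitted parameter set (full two-site model)."""
    return MONKEY_RE


@pytest.fixture
def single_site(re_params) -> ModelParams:
    """Single-plasticity-site special case: eta = gamma = 0."""
    return re_params.single_site()
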