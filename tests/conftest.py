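import pytest

from riverhealth.simulate import GradientScenario


@pytest.fixture
def scenario() -> GradientScenario:
    return GradientScenario(n_sites=12, seed=42)
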