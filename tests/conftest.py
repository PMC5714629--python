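import pytest

from planverify.comparison import ToleranceRules
from planverify.fixtures import make_demo_mutant, make_demo_plan


@pytest.fixture(scope="session")
def rules():
    return ToleranceRules.default()


@pytest.fixture()
def demo_plan():
    return make_demo_plan()


@pytest.fixture()
def demo_mutant(demo_plan):
    return make_demo_mutant(demo_plan)
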