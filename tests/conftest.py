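import pytest

from irprosody.fixtures import fig3_sequence, fig3a_grouping
from irprosody.hierarchy import build_hierarchy
from irprosody.model import Thresholds


@pytest.fixture(scope="session")
def speech():
    return Thresholds.speech()


@pytest.fixture(scope="session")
def music():
    return Thresholds.music()


@pytest.fixture(scope="session")
def fig3_tree(speech):
    return build_hierarchy(fig3_sequence(), [], speech)


@pytest.fixture()
def fig3a_tones():
    return fig3a_grouping()
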