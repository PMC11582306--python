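import numpy as np
import pytest

from rrbias import DesignLayout, QuestionBlock, RandomizationSpec


@pytest.fixture
def rand56() -> RandomizationSpec:
    return RandomizationSpec(5 / 6)


@pytest.fixture
def rand08() -> RandomizationSpec:
    return RandomizationSpec(0.8)


@pytest.fixture
def ely_layout(rand56) -> DesignLayout:
    return DesignLayout([QuestionBlock("ever_last_year", rand56)])


@pytest.fixture
def ely_plus_q_layout(rand56) -> DesignLayout:
    return DesignLayout([QuestionBlock("ever_last_year", rand56),
                         QuestionBlock("single", rand56)])


@pytest.fixture
def two_ely_layout(rand56) -> DesignLayout:
    return DesignLayout([QuestionBlock("ever_last_year", rand56),
                         QuestionBlock("ever_last_year", rand56)])


@pytest.fixture
def subsamples_layout(rand08) -> DesignLayout:
    return DesignLayout([QuestionBlock("single", rand08)], subsamples=True)


@pytest.fixture
def two_q_layout(rand08) -> DesignLayout:
    return DesignLayout([QuestionBlock("single", rand08),
                         QuestionBlock("single", rand08)])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240830)
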