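import numpy as np
import pytest

from bcinquiry.constitutions import Constitution
from bcinquiry.questionnaire import (
    Item,
    QuestionnaireSpec,
    Subscale,
    default_questionnaire,
)


@pytest.fixture(scope="session")
def toy_spec() -> QuestionnaireSpec:
    """Nine items, one single-item subscale per constitution."""
    items = tuple(Item(id=i) for i in range(1, 10))
    subscales = tuple(
        Subscale(constitution=c, item_ids=(int(c) + 1,)) for c in Constitution
    )
    return QuestionnaireSpec(items=items, subscales=subscales)


@pytest.fixture(scope="session")
def ccmq_spec() -> QuestionnaireSpec:
    return default_questionnaire()


@pytest.fixture(scope="session")
def small_original(ccmq_spec):
    """A modest labeled uniform-random dataset on the shipped questionnaire."""
    from bcinquiry.synth import build_original_dataset

    return build_original_dataset(ccmq_spec, m=30_000, seed=20_260)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(11)
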