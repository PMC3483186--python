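import numpy as np
import pytest

from sciophylo.fixtures import load_study_characters, load_study_tree


@pytest.fixture(scope="session")
def study_tree():
    return load_study_tree()


@pytest.fixture(scope="session")
def study_matrix():
    return load_study_characters()


@pytest.fixture()
def rng():
    return np.random.default_rng(20120910)
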