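import pytest

from allerscreen.align import AlignmentParams
from allerscreen.seqio import load_blosum50


@pytest.fixture(scope="session")
def blosum50():
    return load_blosum50()


@pytest.fixture(scope="session")
def params(blosum50):
    return AlignmentParams(matrix=blosum50)
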