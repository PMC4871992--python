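import pytest

from bdva import AcuityScale, AcuityVocabulary


@pytest.fixture(scope="session")
def scale() -> AcuityScale:
    return AcuityScale.default()


@pytest.fixture(scope="session")
def vocab() -> AcuityVocabulary:
    return AcuityVocabulary.default()
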